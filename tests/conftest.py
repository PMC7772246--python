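import numpy as np
import pandas as pd
import pytest

from abilitytraits import factors, preprocess, synthgen
from abilitytraits.datatypes import TRAIT_LABELS


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort with planted truth (seed 0)."""
    cfg = synthgen.default_generator_config(seed=0)
    scores, demo, traits, labels = synthgen.generate_toolbox_cohort(cfg)
    return {"config": cfg, "scores": scores, "demo": demo,
            "traits": traits, "labels": labels}


@pytest.fixture(scope="session")
def scaled_cohort(default_cohort):
    """The default cohort imputed and z-scored on its own reference params."""
    m = synthgen.inject_missingness(default_cohort["scores"], 0.027, seed=1)
    m, _ = preprocess.filter_subjects(m, default_cohort["demo"])
    m = preprocess.impute_mean(m)
    params = preprocess.fit_reference_scaling(m)
    return preprocess.apply_scaling(m, params), params


@pytest.fixture(scope="session")
def fitted_factor_model(scaled_cohort):
    z, _ = scaled_cohort
    return factors.varimax_rotate(factors.fit_factor_model(z, 4))


@pytest.fixture()
def small_traits():
    """778 subjects of standard-normal traits (brain-regression input)."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.standard_normal((778, 4)),
        columns=list(TRAIT_LABELS),
        index=pd.Index([f"S{i:06d}" for i in range(778)], name="subject"),
    )


@pytest.fixture()
def tiny_score_matrix():
    """4 subjects x 3 variables with one missing cell and one sign-flip column."""
    values = pd.DataFrame(
        {
            "walk": [1.0, 2.0, np.nan, 4.0],
            "memory": [2.0, 4.0, 6.0, 8.0],
            "pegboard_time": [10.0, 20.0, 30.0, 40.0],
        },
        index=pd.Index(["a", "b", "c", "d"], name="subject"),
    )
    meta = pd.DataFrame(
        {
            "domain": ["motor", "cognition", "motor"],
            "sign_flip": [False, False, True],
        },
        index=pd.Index(values.columns, name="variable"),
    )
    from abilitytraits.datatypes import ScoreMatrix

    return ScoreMatrix(values, meta)
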