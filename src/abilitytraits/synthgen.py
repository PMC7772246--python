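"""Synthetic cohort generators with planted ground truth.

Every downstream stage of the package (factor analysis, cluster transfer,
brain-feature regression, twin heritability) is exercised on cohorts built
here. The generators emulate the statistical structure of a toolbox-style
normative study: 31 battery variables driven by 4 latent ability traits
through a block-structured loading matrix, a 4-component cluster structure
in trait space, sparse missingness, ACE-structured twin/sibling
correlations, and connectivity features linearly related to two of the
four traits through a sparse coefficient vector. The planted truth (trait
scores, cluster labels, variance components, feature support) is returned
alongside the data so recovery can be scored exactly.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    TRAIT_LABELS,
    BrainFeatureSet,
    ScoreMatrix,
    conn_feature_name,
    upper_triangle_pairs,
)

__all__ = [
    "GeneratorConfig",
    "ACEConfig",
    "BrainFeatureConfig",
    "default_loading_template",
    "default_variable_meta",
    "default_generator_config",
    "default_ace_config",
    "default_brain_config",
    "generate_toolbox_cohort",
    "generate_family_cohort",
    "simulate_ace_pairs",
    "generate_brain_features",
    "generate_ic_maps_and_templates",
    "inject_missingness",
]

# ---------------------------------------------------------------------------
# default fixtures
# ---------------------------------------------------------------------------

# Variable inventory: (name, domain, sign_flip). Four blocks mirroring the
# four ability traits: motor/endurance, emotional, cognitive (incl. two
# sensory tasks), social. Dexterity tasks are completion times, so larger
# raw values mean worse performance (sign_flip).
_VARIABLES: list[tuple[str, str, bool]] = [
    # block 0: motor / endurance (8)
    ("endurance_2min_walk", "motor", False),
    ("endurance_4m_gait_speed", "motor", False),
    ("grip_strength_dom", "motor", False),
    ("grip_strength_nondom", "motor", False),
    ("dexterity_pegboard_dom", "motor", True),
    ("dexterity_pegboard_nondom", "motor", True),
    ("balance_standing", "motor", False),
    ("upper_extremity_strength", "motor", False),
    # block 1: emotional processing (8)
    ("positive_affect", "emotion", False),
    ("general_life_satisfaction", "emotion", False),
    ("meaning_and_purpose", "emotion", False),
    ("emotional_support", "emotion", False),
    ("self_efficacy", "emotion", False),
    ("perceived_stress", "emotion", False),
    ("sadness", "emotion", False),
    ("fear_affect", "emotion", False),
    # block 2: executive / cognitive (9, incl. two sensory tasks)
    ("picture_sequence_memory", "cognition", False),
    ("list_sorting_working_memory", "cognition", False),
    ("pattern_comparison_speed", "cognition", False),
    ("dimensional_card_sort", "cognition", False),
    ("flanker_inhibitory_control", "cognition", False),
    ("picture_vocabulary", "cognition", False),
    ("oral_reading_recognition", "cognition", False),
    ("odor_identification", "sensory", False),
    ("words_in_noise", "sensory", False),
    # block 3: social interaction (6)
    ("friendship", "emotion", False),
    ("loneliness", "emotion", False),
    ("perceived_hostility", "emotion", False),
    ("perceived_rejection", "emotion", False),
    ("instrumental_support", "emotion", False),
    ("social_withdrawal", "emotion", False),
]

_BLOCKS = [range(0, 8), range(8, 16), range(16, 25), range(25, 31)]


def default_variable_meta() -> pd.DataFrame:
    names = [v[0] for v in _VARIABLES]
    return pd.DataFrame(
        {
            "domain": [v[1] for v in _VARIABLES],
            "sign_flip": [v[2] for v in _VARIABLES],
        },
        index=pd.Index(names, name="variable"),
    )


def default_loading_template() -> np.ndarray:
    """Block-structured 31 x 4 loading matrix.

    Primary loadings ramp 0.5-0.9 within each block; a light deterministic
    pattern of cross-loadings (0.10-0.25, always below 0.3) links every
    third variable to the next trait, emulating the mild factorial
    complexity of real battery data.
    """
    n_vars, n_factors = len(_VARIABLES), 4
    L = np.zeros((n_vars, n_factors))
    for f, block in enumerate(_BLOCKS):
        idx = np.array(list(block))
        L[idx, f] = np.linspace(0.5, 0.9, len(idx))
        cross = idx[::3]
        L[cross, (f + 1) % n_factors] = np.linspace(0.10, 0.25, len(cross))
    return L


def _default_cluster_means() -> np.ndarray:
    # one component per trait axis: pairwise distance 4.5*sqrt(2) ~ 6.36,
    # i.e. >= 6 component-sd at the default within-cluster sd of 1.0.
    # (With K components the between-cluster covariance has rank K-1, so
    # the within-cluster spread must carry the remaining trait dimension;
    # axis-aligned means keep every trait dimension well expressed.)
    return 4.5 * np.eye(4)


@dataclass
class GeneratorConfig:
    """Study conditions for the toolbox-style cohort generator."""

    n_subjects: int = 1369
    n_vars: int = 31
    n_factors: int = 4
    loading_template: np.ndarray = field(default_factory=default_loading_template)
    uniquenesses: np.ndarray = field(default_factory=lambda: np.linspace(0.3, 0.5, 31))
    cluster_means: np.ndarray = field(default_factory=_default_cluster_means)
    cluster_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.25, 0.25, 0.20])
    )
    cluster_sd: np.ndarray = field(default_factory=lambda: np.full(4, 1.0))
    missing_rate: float = 0.027
    # demographic composition per cluster: cluster 1 mostly male, cluster 4
    # older — free parameters emulating the qualitative covariate pattern
    cluster_p_male: np.ndarray = field(
        default_factory=lambda: np.array([0.65, 0.38, 0.38, 0.45])
    )
    cluster_age_mean: np.ndarray = field(
        default_factory=lambda: np.array([38.0, 40.0, 42.0, 62.0])
    )
    cluster_age_sd: np.ndarray = field(default_factory=lambda: np.full(4, 10.0))
    seed: int = 0

    def validate(self) -> None:
        L = np.asarray(self.loading_template, dtype=float)
        if L.shape != (self.n_vars, self.n_factors):
            raise ValueError(
                f"loading_template shape {L.shape} != ({self.n_vars}, {self.n_factors})"
            )
        if np.linalg.matrix_rank(L) < self.n_factors:
            raise ValueError(
                "loading_template is rank deficient: planted factors would be "
                "unidentifiable; provide a full-column-rank template"
            )
        u = np.asarray(self.uniquenesses, dtype=float)
        if u.shape != (self.n_vars,) or (u <= 0).any():
            raise ValueError("uniquenesses must be positive, one per variable")
        w = np.asarray(self.cluster_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12 or (w < 0).any():
            raise ValueError("cluster_weights must be a simplex vector (sum 1)")
        K = len(w)
        if np.asarray(self.cluster_means).shape != (K, self.n_factors):
            raise ValueError("cluster_means must be K x n_factors")
        if not 0.0 <= self.missing_rate <= 0.3:
            raise ValueError("missing_rate must lie in [0, 0.3]")


def default_generator_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides)


@dataclass
class ACEConfig:
    """Variance components and pair counts for the family-cohort generator.

    A, C and E are the additive-genetic, shared-environment and non-shared
    fractions of trait variance; they must sum to one.
    """

    A: float = 0.31
    C: float = 0.34
    E: float = 0.35
    n_mz_pairs: int = 74
    n_dz_pairs: int = 52
    n_sib_pairs: int = 274
    n_half_pairs: int = 12
    n_unrelated: int = 100
    seed: int = 0

    def validate(self) -> None:
        comps = np.array([self.A, self.C, self.E], dtype=float)
        if (comps < 0).any():
            raise ValueError(f"negative variance component in A/C/E: {comps}")
        if abs(comps.sum() - 1.0) > 1e-12:
            raise ValueError(f"A + C + E must equal 1, got {comps.sum()!r}")


def default_ace_config(**overrides) -> ACEConfig:
    return replace(ACEConfig(), **overrides)


# additive-genetic correlation by relationship (standard additive genetics)
GENETIC_CORRELATION = {
    "MZ": 1.0,
    "DZ": 0.5,
    "fullsib": 0.5,
    "halfsib": 0.25,
    "unrelated": 0.0,
}

RELATIONS = ("MZ", "DZ", "fullsib", "halfsib", "unrelated")


def _default_true_coefficients(n_ics: int = 50) -> pd.DataFrame:
    """Sparse trait -> connectivity coefficient matrix, 19-feature support.

    Motor-endurance drives 10 edges and Executive and cognitive function 9,
    each with coefficient magnitude 0.5 and alternating sign; the two
    emotional/social traits drive nothing, matching a study design where
    only two traits have a connectivity substrate.
    """
    pairs = upper_triangle_pairs(n_ics)
    names = [conn_feature_name(i, j) for i, j in pairs]
    n_feat = len(names)
    if n_feat < 19:
        raise ValueError("need at least 19 connectivity features for the default support")
    coefs = pd.DataFrame(0.0, index=list(TRAIT_LABELS), columns=names)
    support = np.unique(np.linspace(0, n_feat - 1, 19).round().astype(int))
    for k, idx in enumerate(support[:10]):
        coefs.loc[TRAIT_LABELS[0], names[idx]] = 0.5 * (-1) ** k
    for k, idx in enumerate(support[10:]):
        coefs.loc[TRAIT_LABELS[2], names[idx]] = 0.5 * (-1) ** (k + 1)
    return coefs


@dataclass
class BrainFeatureConfig:
    """Conditions for the connectivity-feature generator."""

    n_ics: int = 50
    true_coefficients: pd.DataFrame = field(default_factory=_default_true_coefficients)
    noise_sd: float = 1.0
    n_morphology: int = 20
    ridge_rho: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        n_feat = self.n_ics * (self.n_ics - 1) // 2
        if self.true_coefficients.shape[1] != n_feat:
            raise ValueError(
                f"true_coefficients has {self.true_coefficients.shape[1]} columns, "
                f"expected n_ics(n_ics-1)/2 = {n_feat}"
            )
        if self.ridge_rho <= 0:
            raise ValueError("ridge_rho must be > 0")

    @property
    def true_support(self) -> list[str]:
        """Names of connectivity features with a nonzero planted coefficient."""
        nz = (self.true_coefficients != 0).any(axis=0)
        return list(self.true_coefficients.columns[nz])


def default_brain_config(**overrides) -> BrainFeatureConfig:
    return replace(BrainFeatureConfig(), **overrides)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _subject_ids(n: int, prefix: str = "S") -> pd.Index:
    return pd.Index([f"{prefix}{i:06d}" for i in range(n)], name="subject")


def _traits_frame(arr: np.ndarray, index: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(arr, index=index, columns=list(TRAIT_LABELS)[: arr.shape[1]])


def generate_toolbox_cohort(
    config: GeneratorConfig,
) -> tuple[ScoreMatrix, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw a toolbox-style cohort from the planted factor/cluster model.

    Trait scores are drawn from the K-component spherical Gaussian mixture,
    observed scores are ``loading_template @ traits`` plus diagonal Gaussian
    noise, and demographics (age 18-85, binary gender) follow the
    cluster-dependent composition in the config.

    Returns
    -------
    (scores, demographics, traits_true, cluster_labels_true)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K = len(config.cluster_weights)

    labels = rng.choice(K, size=config.n_subjects, p=np.asarray(config.cluster_weights))
    means = np.asarray(config.cluster_means, dtype=float)
    sds = np.asarray(config.cluster_sd, dtype=float)
    traits = means[labels] + rng.standard_normal(
        (config.n_subjects, config.n_factors)
    ) * sds[labels][:, None]

    L = np.asarray(config.loading_template, dtype=float)
    noise = rng.standard_normal((config.n_subjects, config.n_vars)) * np.sqrt(
        np.asarray(config.uniquenesses, dtype=float)
    )
    observed = traits @ L.T + noise

    meta = default_variable_meta()
    if config.n_vars != len(meta):
        names = [f"var_{i:02d}" for i in range(config.n_vars)]
        meta = pd.DataFrame(
            {"domain": ["cognition"] * config.n_vars,
             "sign_flip": [False] * config.n_vars},
            index=pd.Index(names, name="variable"),
        )
    ids = _subject_ids(config.n_subjects)
    scores = ScoreMatrix(
        pd.DataFrame(observed, index=ids, columns=meta.index), meta
    )

    age = np.clip(
        rng.normal(config.cluster_age_mean[labels], config.cluster_age_sd[labels]),
        18.0,
        85.0,
    )
    gender = (rng.random(config.n_subjects) < config.cluster_p_male[labels]).astype(int)
    demo = pd.DataFrame({"age": age, "gender": gender}, index=ids)

    return scores, demo, _traits_frame(traits, ids), labels


def simulate_ace_pairs(
    acfg: ACEConfig, n_traits: int = 1, rng: np.random.Generator | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """Draw ACE-structured trait values for every configured pair type.

    Per trait and subject the value is ``sqrt(A) g + sqrt(C) c + sqrt(E) e``
    with the additive component g correlated across pair members at the
    relationship's genetic overlap (1 MZ, 0.5 DZ and full sibs, 0.25 half
    sibs, 0 unrelated), the shared component c identical within a pair, and
    e independent. Returns, per relation, arrays ``values`` and ``g`` of
    shape (n_pairs, 2, n_traits).
    """
    acfg.validate()
    if rng is None:
        rng = np.random.default_rng(acfg.seed)
    counts = {
        "MZ": acfg.n_mz_pairs,
        "DZ": acfg.n_dz_pairs,
        "fullsib": acfg.n_sib_pairs,
        "halfsib": acfg.n_half_pairs,
        "unrelated": acfg.n_unrelated // 2,
    }
    sqA, sqC, sqE = np.sqrt([acfg.A, acfg.C, acfg.E])
    out: dict[str, dict[str, np.ndarray]] = {}
    for rel, n_pairs in counts.items():
        r = GENETIC_CORRELATION[rel]
        shape = (n_pairs, n_traits)
        g_shared = rng.standard_normal(shape)
        g_own = rng.standard_normal((n_pairs, 2, n_traits))
        g = np.sqrt(r) * g_shared[:, None, :] + np.sqrt(1.0 - r) * g_own
        c = np.repeat(rng.standard_normal(shape)[:, None, :], 2, axis=1)
        e = rng.standard_normal((n_pairs, 2, n_traits))
        out[rel] = {"values": sqA * g + sqC * c + sqE * e, "g": g}
    return out


def generate_family_cohort(
    gcfg: GeneratorConfig, acfg: ACEConfig
) -> tuple[ScoreMatrix, pd.DataFrame, dict]:
    """Build a twin/sibling cohort with ACE-structured traits.

    Traits follow the ACE decomposition (no cluster structure: family
    resemblance, not subgrouping, is what this cohort tests); observed
    scores reuse the loading template and uniquenesses from ``gcfg``.

    Returns
    -------
    scores : ScoreMatrix
    kinship : pandas.DataFrame
        Columns subject_a, subject_b, relation, same_gender.
    truth : dict
        ``traits`` (DataFrame), ``g`` (DataFrame of additive components),
        ``components`` (the generating A, C, E), ``gender`` (Series).
    """
    gcfg.validate()
    acfg.validate()
    rng = np.random.default_rng(acfg.seed)
    sim = simulate_ace_pairs(acfg, n_traits=gcfg.n_factors, rng=rng)

    rows_values, rows_g, kin_records = [], [], []
    genders = []
    idx = 0
    ids: list[str] = []
    for rel in RELATIONS:
        block = sim[rel]
        n_pairs = block["values"].shape[0]
        for p in range(n_pairs):
            a, b = f"S{idx:06d}", f"S{idx + 1:06d}"
            idx += 2
            ids += [a, b]
            rows_values += [block["values"][p, 0], block["values"][p, 1]]
            rows_g += [block["g"][p, 0], block["g"][p, 1]]
            if rel == "MZ":
                ga = gb = int(rng.integers(2))
            else:
                ga, gb = int(rng.integers(2)), int(rng.integers(2))
            genders += [ga, gb]
            if rel != "unrelated":
                kin_records.append(
                    {"subject_a": a, "subject_b": b, "relation": rel,
                     "same_gender": ga == gb}
                )

    index = pd.Index(ids, name="subject")
    traits = _traits_frame(np.vstack(rows_values), index)
    g_comp = _traits_frame(np.vstack(rows_g), index)

    L = np.asarray(gcfg.loading_template, dtype=float)
    noise = rng.standard_normal((len(index), gcfg.n_vars)) * np.sqrt(
        np.asarray(gcfg.uniquenesses, dtype=float)
    )
    observed = traits.to_numpy() @ L.T + noise
    meta = default_variable_meta()
    scores = ScoreMatrix(pd.DataFrame(observed, index=index, columns=meta.index), meta)

    kinship = pd.DataFrame(kin_records, columns=["subject_a", "subject_b", "relation", "same_gender"])
    truth = {
        "traits": traits,
        "g": g_comp,
        "components": {"A": acfg.A, "C": acfg.C, "E": acfg.E},
        "gender": pd.Series(genders, index=index, name="gender"),
    }
    return scores, kinship, truth


def generate_brain_features(
    traits: pd.DataFrame, bcfg: BrainFeatureConfig
) -> BrainFeatureSet:
    """Connectivity features linearly driven by traits plus decoys.

    Each subject's symmetric ``n_ics x n_ics`` matrix has upper-triangle
    entries ``baseline + sum_t traits[t] * coef[t, f] + noise``; morphology
    columns are appended as pure-noise decoys. The per-feature baseline is
    a fixed draw under the config seed, emulating a population-mean
    connectome.
    """
    bcfg.validate()
    if not np.isfinite(traits.to_numpy()).all():
        raise ValueError("trait scores must be finite")
    rng = np.random.default_rng(bcfg.seed)
    n_sub = traits.shape[0]
    names = list(bcfg.true_coefficients.columns)
    n_feat = len(names)

    baseline = rng.normal(0.0, 0.1, size=n_feat)
    coefs = bcfg.true_coefficients.reindex(traits.columns).fillna(0.0).to_numpy()
    conn = (
        baseline
        + traits.to_numpy() @ coefs
        + rng.standard_normal((n_sub, n_feat)) * bcfg.noise_sd
    )

    morph_names = [f"morph_{k:02d}" for k in range(bcfg.n_morphology)]
    morph = rng.standard_normal((n_sub, bcfg.n_morphology))

    features = pd.DataFrame(
        np.hstack([conn, morph]), index=traits.index, columns=names + morph_names
    )
    pairs = upper_triangle_pairs(bcfg.n_ics)
    meta = pd.DataFrame(
        {
            "kind": ["connectivity"] * n_feat + ["morphology"] * bcfg.n_morphology,
            "ic_pair": [f"{i}-{j}" for i, j in pairs] + [""] * bcfg.n_morphology,
        },
        index=pd.Index(names + morph_names, name="feature"),
    )
    return BrainFeatureSet(
        features,
        meta,
        provenance={
            "n_ics": bcfg.n_ics,
            "netmat_variant": "partial",
            "ridge_rho": bcfg.ridge_rho,
            "true_support": bcfg.true_support,
        },
    )


def connectivity_matrix(fs: BrainFeatureSet, subject: str) -> np.ndarray:
    """Reassemble one subject's symmetric zero-diagonal connectivity matrix."""
    n_ics = fs.provenance["n_ics"]
    mat = np.zeros((n_ics, n_ics))
    row = fs.features.loc[subject]
    for (i, j) in upper_triangle_pairs(n_ics):
        v = row[conn_feature_name(i, j)]
        mat[i, j] = mat[j, i] = v
    return mat


def generate_ic_maps_and_templates(
    n_ics: int = 10,
    n_templates: int = 8,
    n_voxels: int = 2000,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """IC spatial maps as noisy scaled copies of disjoint network templates.

    Templates partition the voxel axis into ``n_templates`` contiguous
    binary supports. IC ``k`` copies template ``k % n_templates`` with a
    random positive amplitude plus white noise. Returns
    ``(ic_maps, templates, truth_labels)``.
    """
    if n_voxels < n_templates:
        raise ValueError("n_voxels must be >= n_templates")
    if n_templates > n_ics and n_ics < 1:
        raise ValueError("need at least one IC")
    rng = np.random.default_rng(seed)
    templates = np.zeros((n_templates, n_voxels))
    bounds = np.linspace(0, n_voxels, n_templates + 1).astype(int)
    for t in range(n_templates):
        templates[t, bounds[t]: bounds[t + 1]] = 1.0
    truth = [k % n_templates for k in range(n_ics)]
    amplitudes = rng.uniform(1.5, 3.0, size=n_ics)
    maps = amplitudes[:, None] * templates[truth] + rng.standard_normal(
        (n_ics, n_voxels)
    ) * noise_sd
    return maps, templates, truth


def inject_missingness(m: ScoreMatrix, rate: float, seed: int = 0) -> ScoreMatrix:
    """Mask each cell independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate <= 0.3:
        raise ValueError(
            f"missing rate {rate} outside [0, 0.3]; cohorts with more than 30% "
            "missingness are excluded upstream, not imputed"
        )
    out = m.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < rate
    vals = out.values.to_numpy(dtype=float, copy=True)
    vals[mask] = np.nan
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out
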