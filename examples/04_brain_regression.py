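"""Stability-selected L1 regression of traits on connectivity features.

Builds 778 subjects with 50-IC connectivity features in which 19 edges
carry a planted linear signal for two traits, runs a 100-split lasso
ensemble at the sparse interpretation penalty, and scores the
80%-prevalence feature list against the planted support.
"""

import numpy as np
import pandas as pd

from abilitytraits import brainreg, synthgen
from abilitytraits.datatypes import TRAIT_LABELS

rng = np.random.default_rng(0)
traits = pd.DataFrame(
    rng.standard_normal((778, 4)), columns=list(TRAIT_LABELS),
    index=pd.Index([f"S{i:06d}" for i in range(778)], name="subject"),
)
bcfg = synthgen.default_brain_config(seed=1)
features = synthgen.generate_brain_features(traits, bcfg)
print(f"feature table: {features.features.shape[1]} features "
      f"({bcfg.n_ics} ICs -> {bcfg.n_ics*(bcfg.n_ics-1)//2} edges + decoys)")

cfg = brainreg.RegressionConfig(seed=2)
ens = brainreg.run_ensemble(features, traits, cfg, n_runs=100,
                            alpha_override=cfg.lambda_interpret)
print("mean out-of-sample r^2 per trait:")
print(ens.oos_r2_mean.round(3).to_string())

stable = brainreg.prevalent_features(ens, feature_meta=features.feature_meta)
truth = set(bcfg.true_support)
selected = set(stable[TRAIT_LABELS[0]].index) | set(stable[TRAIT_LABELS[2]].index)
tp = len(selected & truth)
print(f"\nstable features: {len(selected)} selected, {len(truth)} planted, "
      f"precision {tp/max(len(selected),1):.2f}, recall {tp/len(truth):.2f}")
# only the two traits with a planted connectivity substrate predict out of
# sample; the emotional/social traits stay near r^2 = 0 by construction
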