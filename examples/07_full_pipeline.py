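"""Run the full chain in one call (scaled-down sizes for a quick demo).

Equivalent CLI: abilitytraits all --seed 7 --out scratch/demo
"""

import json

from abilitytraits.pipeline import PipelineConfig, run_full_pipeline
from abilitytraits.synthgen import _default_true_coefficients

cfg = PipelineConfig(
    seed=7,
    n_reference=600,
    ace_overrides=dict(n_mz_pairs=60, n_dz_pairs=45, n_sib_pairs=90,
                       n_half_pairs=10, n_unrelated=60),
    brain_overrides=dict(n_ics=20,
                         true_coefficients=_default_true_coefficients(20)),
    n_stability_subsets=5,
    ensemble_runs=30,
    candidate_runs=2,
    n_boot=100,
)
manifest = run_full_pipeline(cfg, "scratch/demo")
print(json.dumps(manifest["stages"], indent=1, default=str))
# artifacts (trait scores, cluster labels, stable features with network
# labels, the ACE table, kinship distance profiles) are in scratch/demo/
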