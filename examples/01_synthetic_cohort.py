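"""Generate a toolbox-style cohort with planted structure.

Draws 1,369 subjects whose 31 battery scores are driven by 4 latent
ability traits through a block-structured loading matrix, with a
4-component cluster structure in trait space and 2.7% missingness,
then prints what was planted.
"""

from abilitytraits import synthgen

cfg = synthgen.default_generator_config(seed=0)
scores, demo, traits_true, labels_true = synthgen.generate_toolbox_cohort(cfg)
scores = synthgen.inject_missingness(scores, cfg.missing_rate, seed=1)

print(f"cohort: {scores.n_subjects} subjects x {scores.n_variables} variables")
print(f"missing fraction: {scores.mask.to_numpy().mean():.4f} (target {cfg.missing_rate})")
print("planted cluster sizes:", [int((labels_true == k).sum()) for k in range(4)])
print("\nfirst variables and their domains:")
print(scores.variable_meta.head(6))
# The true trait scores and cluster labels are returned so that recovery by
# the factor-analysis and clustering stages can be scored exactly.
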