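"""Label independent components with canonical network templates.

Each IC map is a noisy scaled copy of one template's support; Pearson
correlation against every template recovers the planted labels.
"""

from abilitytraits import netannot, synthgen

maps, templates, truth = synthgen.generate_ic_maps_and_templates(
    n_ics=10, n_templates=8, n_voxels=2000, noise_sd=0.3, seed=0
)
names = ["executive_control", "default_mode", "salience", "precuneus",
         "sensorimotor", "language", "auditory", "visual"]
table = netannot.match_templates(maps, templates, names)
print(table[["label", "correlation"]].round(3))
correct = sum(table["label"].iloc[k] == names[truth[k]] for k in range(len(truth)))
print(f"\n{correct}/{len(truth)} ICs labeled with their planted network")
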