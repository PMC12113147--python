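"""Batch-fit the N/P-ratio series and recover its structural trends.

The nitrogen-to-phosphate (N/P) ratio is the key formulation variable of
mRNA-LNPs.  This example simulates one noisy curve per N/P preset (3:1 to
8:1), refits all of them in a batch, and prints the standard parameter table.
The expected physics: sigma (size spread) shrinks with increasing N/P while
W_Peak (quasi-Bragg width) grows — more uniform particles, less ordered
internal mRNA-lipid packing.
"""

from lnpsaxs import (
    FitConfig,
    NoiseModel,
    batch_fit,
    generate_curve,
    make_initial_from_truth,
    preset,
)

names = ["table2-NP3", "table2-NP5", "table2-NP6", "table2-NP7", "table2-NP8"]
curves, initials = {}, {}
for i, name in enumerate(names):
    truth = preset(name)
    curves[name] = generate_curve(truth, noise=NoiseModel(level=0.01, seed=30 + i))
    initials[name] = make_initial_from_truth(truth, relative=0.10, seed=30 + i)

config = FitConfig.for_params(preset(names[0]))
out = batch_fit(curves, config, initials)

cols = ["sigma", "R0", "t1", "C_Gaussian", "W_Peak"]
print(out.table.loc[names, cols].round(3).to_string())
print("\nsigma falls from N/P 3:1 to 8:1 (more uniform particles) while the"
      "\nquasi-Bragg peak broadens (less ordered internal packing).")
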