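"""How many mice per model does a categorical readout need?

Subsamples n mice from each model's treated group, takes the majority
response, and scores agreement with the full-group majority (1000 draws).
Accuracy rises with n; the per-category breakdown shows the minority
categories are the fragile ones.
"""

from mctkit import SimConfig, categorical_accuracy, generate_mct

dataset, _ = generate_mct(SimConfig(n_models=20, n_mice_per_arm=4), seed=9)
curve = categorical_accuracy(
    dataset, "recist", n_values=(1, 3), replications=1000, seed=10,
    arm="treatment",
)

print("subsample size -> unweighted mean accuracy across categories")
for n, acc in curve.unweighted_mean_accuracy.items():
    print(f"  n = {n}: {acc:.3f}")
print("\nper-category accuracy (mean over models with that majority):")
print(curve.to_frame().to_string(index=False))
print(
    "\nAn accuracy of 0.9 at n = 1 means a single mouse reproduces the "
    "full-group\nmajority call 90% of the time for models of that category."
)
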