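"""Generate a synthetic labelled cohort and inspect its grade mix.

The truth model is the packaged trained-reference rule base; features are
drawn uniformly over each attribute's referential range, labelled by the
truth model, then blurred with 2% observation noise.
"""

import numpy as np

from brb_rehab import SimulationConfig, reference_trained_rulebase, simulate_dataset, split

truth = reference_trained_rulebase()
cfg = SimulationConfig(n_records=2000, seed=42)
cohort = simulate_dataset(truth, cfg)
train_set, test_set = split(cohort, cfg.train_fraction, cfg.seed)

print(f"cohort: {len(cohort)} records -> {len(train_set)} train / {len(test_set)} test")
counts = np.bincount(cohort.grades, minlength=5)[1:]
for label, c in zip(truth.grade_labels, counts):
    print(f"  grade {label:>3}: {c:5d} records ({100 * c / len(cohort):.1f}%)")
print("\nUniform feature sampling over the referential ranges does not give a")
print("uniform grade mix; use scheme='stratified' to target one.")
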