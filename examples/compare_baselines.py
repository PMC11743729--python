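"""Benchmark the rule-base model against generic classifiers.

Fits a feed-forward neural network and an RBF support-vector classifier on
the same training split and scores all three on held-out records.  The
baselines see only (features, grade) pairs; the rule base additionally
encodes the expert grid structure.
"""

from brb_rehab import (
    BRBAssessor,
    SimulationConfig,
    compare,
    comparison_table,
    initial_expert_rulebase,
    neural_network_baseline,
    reference_trained_rulebase,
    simulate_dataset,
    split,
    svm_baseline,
)

truth = reference_trained_rulebase()
cohort = simulate_dataset(truth, SimulationConfig(n_records=1000, seed=3))
train_set, test_set = split(cohort, 0.8, seed=3)

models = {
    "brb (expert init)": BRBAssessor(initial_expert_rulebase()),
    "neural network": neural_network_baseline(seed=0).fit(train_set),
    "svm": svm_baseline(seed=0).fit(train_set),
}
reports = compare(models, test_set, truth.grade_utilities)
print(comparison_table(reports).to_string())
print("\naccuracy = fraction of correctly graded records; mse = squared error")
print("on the 1-4 utility scale (continuous for the rule base, discrete for")
print("the baselines).")
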