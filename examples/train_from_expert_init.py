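"""Learn rule-base parameters from labelled data.

Simulates a cohort from the trained-reference truth model, then trains the
initial expert rule base (theta = delta = 1) by constrained MSE
minimization.  The cohort is kept small here so the example runs in a few
seconds; the full study design uses 1,600 training records.
"""

from brb_rehab import (
    SimulationConfig,
    TrainingConfig,
    evaluate,
    initial_expert_rulebase,
    reference_trained_rulebase,
    simulate_dataset,
    split,
    train,
)

truth = reference_trained_rulebase()
init = initial_expert_rulebase()

cohort = simulate_dataset(truth, SimulationConfig(n_records=500, seed=7))
train_set, test_set = split(cohort, 0.8, seed=7)

fitted, report = train(init, train_set, TrainingConfig(max_iter=15))

print(f"training MSE: {report.initial_mse:.4f} -> {report.final_mse:.4f} "
      f"({report.n_iterations} iterations)")
print(f"held-out accuracy: expert init {evaluate(init, test_set).accuracy:.3f}, "
      f"trained {evaluate(fitted, test_set).accuracy:.3f}")
print("\nMSE is measured between the model's expected utility and the utility")
print("of each record's true grade; accuracy is the fraction of records whose")
print("nearest-utility grade matches the label.")
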