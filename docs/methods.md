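# Methods

## Model

The assessor is a belief rule base (BRB) over M = 3 antecedent attributes
(ARTUL, RTT, MAMS), each quantized by J = 3 strictly increasing referential
values, with N = 4 outcome grades I–IV carrying utilities u = {1, 2, 3, 4}.
The rule base is the full antecedent grid (L = 27 rules, one per
combination, listed with the last attribute varying fastest). Each rule has
a weight θ_k ∈ [0, 1], and a consequent belief vector β_{·,k} with
β_{j,k} ∈ [0, 1] and Σ_j β_{j,k} ≤ 1 — rules whose beliefs sum to less
than 1 are *incomplete* and leave residual mass unassigned, which the
evidential-reasoning (ER) combination tracks explicitly. Attributes carry
weights δ_i ∈ [0, 1].

Inference assumptions worth stating:

- **Piecewise-linear matching only.** Matching degrees come from linear
  interpolation between the two bracketing referential values; no other
  membership shapes are supported. Consequently at most two adjacent
  referential values per attribute are active, and at most 2^M = 8 rules
  fire for any input.
- **Independent attributes in activation.** The activation weight
  multiplies per-attribute matching degrees raised to normalized attribute
  weights δ̄_i = δ_i / max_j δ_j; no attribute interactions are modelled
  outside the rule consequents.
- **ER normalizer.** The analytic ER form uses the factor N − 1 (number of
  grades minus one) in its normalizing constant μ. This is the only choice
  under which a one-hot activation reproduces the activated rule's beliefs
  exactly and complete rules conserve belief mass; both properties are
  enforced by tests, and the analytic form is cross-checked against an
  independent recursive two-source combination oracle to 1e-10.

## Numerical and design choices

- **Out-of-range inputs** clamp to the nearest boundary referential value
  (matching degree 1 there). This preserves the per-attribute sum-to-1
  invariant; extrapolation beyond the expert grid has no defined meaning.
- **Zero matching degrees** annihilate a rule's activation whenever the
  attribute has positive normalized weight. The 0⁰ = 1 convention is used
  only for a genuinely zero-weight attribute, where x⁰ = 1 removes the
  attribute from the product.
- **Incomplete aggregated beliefs** feed the expected utility as-is by
  default (Σ u_j β̂_j over the available mass); a `renormalize` option
  divides by the total mass first. The default keeps the trained reference
  rule base's published behaviour reproducible to the printed digit.
- **Grade assignment** is nearest-utility with ties broken toward the
  lower (healthier) grade. With utilities {1, 2, 3, 4} this is fixed-width
  binning at the midpoints 1.5, 2.5, 3.5.
- **Belief-sum tolerance** is 1e-9 absolute everywhere.

## Training

Parameters pack into one vector [θ₁..θ_L, δ₁..δ_M, β₁,₁..β_{L,N}]
(138 entries). The objective is the mean squared error between the model's
expected utility and each record's target utility yʳ = u(grade). The
optimizer is scipy's SLSQP (sequential quadratic programming, the same
family as MATLAB's `fmincon`) with finite-difference gradients, box
constraints [0, 1] on every coordinate and one linear inequality
Σ_j β_{j,k} ≤ 1 per rule. Referential values and grade utilities are fixed
— they are not learnable.

- Defaults: ftol 1e-6, 500 iterations maximum, single start; optional
  seeded multi-start keeps the best final objective.
- Infeasible initializations are repaired before optimization: clip to the
  boxes, then scale any rule's belief vector down to sum 1. The same
  projection guards every objective evaluation, so line-search excursions
  outside the feasible set cannot produce invalid rule bases.
- An accept-if-better guard returns the repaired initialization when the
  optimizer ends at a worse objective, making training monotone by
  construction; the report flags when this fired.
- δ is bounded to [0, 1] like θ and β. Since activation normalizes δ by
  its maximum, δ's absolute scale is irrelevant; the box just fixes a
  gauge. Individual parameter blocks (θ, δ, β) can be frozen.
- Training is deterministic given init, data and config: SLSQP and the
  finite-difference scheme involve no randomness.

The replication experiments (acceptance tests and `scripts/acceptance.py`)
use a 30-iteration budget per fit. On the 1,600-record design this
typically cuts training MSE by ~20% and is the point of clearly
diminishing returns for this landscape; the library default stays at 500
for users fitting from poorer initializations.

## Synthetic cohorts

No patient-level dataset is publicly available, so cohorts are simulated.
The generator's defaults mirror the original study design: 2,000 records,
split 1,600 train / 400 test, with the packaged reference trained rule
base as the truth model (so simulated cohorts plausibly resemble the study
population).

- Features are drawn uniformly over each attribute's referential range
  (`uniform` scheme) or rejection-sampled to hit a target grade mix
  (`stratified`, default uniform over the four grades — the study's class
  balance is unreported).
- Labels are the truth model's own classification of the noise-free
  features. Label noise (default 0) flips each label to a uniformly drawn
  other grade. Observation noise (default Gaussian, σ = 2% of each
  attribute's referential range) is added to the features *after*
  labelling and clamped back into range, emulating sensor error on the
  robot's torque/EMG channels.
- Everything is reproducible from a single seed.

What the generator does **not** emulate: biomechanics (torque profiles,
fatigue, EMG waveforms), within-patient longitudinal correlation
(records are i.i.d.), demographic covariates, and any misspecification of
the rule-base family itself — the truth model *is* a BRB, so parameter
recovery on these cohorts shows the optimizer and inference machinery
work, not that a BRB fits real patients. Accuracies measured here
(mid-90s% held out) are accordingly ceilinged by construction and say
nothing quantitative about clinical accuracy.

## Evaluation

Accuracy is computed on discrete grades (fraction of records whose
predicted grade matches the label); MSE on the 1–4 utility scale, using
the continuous expected utility for the BRB and the predicted grade's
utility for discrete baselines. The comparison harness wraps scikit-learn
classifiers — a feed-forward network (one hidden layer of 16 units, 2,000
iterations) and an RBF support-vector classifier (C = 1) — behind the same
predict-grades interface, with fixed seeds. These hyperparameters are
package choices; the original comparison published none.

## Known limitations

- The rule base must be a full grid; sparse or learned rule structures are
  out of scope, as are membership functions other than piecewise-linear.
- Finite-difference SQP is a local method: from a poor initialization it
  can stall at local minima; multi-start mitigates but does not remove
  this.
- The utility-targeted MSE objective only pushes records toward their
  grade's utility value; it does not directly optimize classification
  accuracy, so small MSE gains can occasionally trade against held-out
  accuracy at small sample sizes.
- With all-zero rule weights, or pathological inputs activating no rule,
  inference raises an explicit no-rule-activated error rather than
  guessing.
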