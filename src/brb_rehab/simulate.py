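"""Synthetic labelled cohorts for the upper-limb assessment model.

No patient-level dataset is publicly available for this model, so every
other module is exercised on simulated cohorts: feature vectors (ARTUL, RTT,
MAMS) drawn over the referential ranges, labelled with the grade a chosen
*truth* rule base assigns, optionally corrupted by label flips and Gaussian
observation noise.  The default configuration mirrors the original study
design: 2,000 records split 1,600 / 400 into train and test sets, with the
published trained parameters as the truth model.

The generator works in grade space (the four assessed health grades I-IV);
it makes no attempt at biomechanical realism — torque, training time and
muscle-strength amplitude are sampled as abstract quantities within their
referential ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BeliefRuleBase, assess_batch

__all__ = [
    "SimulationConfig",
    "LabelledDataset",
    "GradeUnreachableError",
    "simulate_dataset",
    "split",
    "perturb_rulebase",
]


class GradeUnreachableError(RuntimeError):
    """Stratified rejection sampling exhausted its budget for some grade."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one simulated cohort.

    Parameters
    ----------
    n_records:
        Cohort size (default 2,000, the original study's collection size).
    train_fraction:
        Fraction routed to the training split by :func:`split` (default 0.8,
        i.e. 1,600 / 400).
    scheme:
        ``"uniform"`` samples each attribute independently and uniformly over
        its referential range; ``"stratified"`` rejection-samples until the
        truth model's grade matches a target grade drawn from
        ``grade_proportions``.
    label_noise:
        Probability of flipping each label to a uniformly drawn *other*
        grade (default 0).
    feature_noise_scale:
        Standard deviation of Gaussian observation noise added to each
        feature *after* labelling, as a fraction of that attribute's
        referential range (default 0.02); features are clamped back into
        range. Set to 0 for noise-free features.
    grade_proportions:
        Target grade mix for the stratified scheme; default uniform over the
        four grades.
    seed:
        Seed for the single generator driving all randomness.
    """

    n_records: int = 2000
    train_fraction: float = 0.8
    scheme: str = "uniform"
    label_noise: float = 0.0
    feature_noise_scale: float = 0.02
    grade_proportions: tuple[float, ...] | None = None
    seed: int = 0
    max_rejection_rounds: int = 1000

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.scheme not in ("uniform", "stratified"):
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must lie in [0, 1)")
        if self.feature_noise_scale < 0:
            raise ValueError("feature_noise_scale must be nonnegative")


@dataclass(frozen=True)
class LabelledDataset:
    """Feature records with (optional) true grades.

    ``features`` is (T, M) in attribute units; ``grades`` is (T,) of 1-based
    grade indices, or ``None`` for an unlabelled dataset.
    """

    features: np.ndarray
    grades: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {f.shape}")
        object.__setattr__(self, "features", f)
        if self.grades is not None:
            g = np.asarray(self.grades, dtype=int)
            if g.shape != (f.shape[0],):
                raise ValueError("grades must align with features")
            object.__setattr__(self, "grades", g)

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def is_labelled(self) -> bool:
        return self.grades is not None

    def target_utilities(self, brb: BeliefRuleBase) -> np.ndarray:
        """y^r per record: the utility of the labelled grade, u(D_g)."""
        if self.grades is None:
            raise ValueError("dataset is unlabelled")
        return brb.grade_utilities[self.grades - 1]

    def subset(self, idx: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(
            features=self.features[idx],
            grades=None if self.grades is None else self.grades[idx],
        )

    def to_frame(self, columns=("artul", "rtt", "mams")) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(columns))
        if self.grades is not None:
            df["grade"] = self.grades
        return df


def _ranges(brb: BeliefRuleBase) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([a.ref_values[0] for a in brb.attributes])
    hi = np.array([a.ref_values[-1] for a in brb.attributes])
    return lo, hi


def simulate_dataset(truth: BeliefRuleBase, cfg: SimulationConfig) -> LabelledDataset:
    """Draw a labelled cohort from a truth rule base.

    Features are sampled per ``cfg.scheme``, labelled by the truth model's
    classification, then labels are flipped with probability
    ``cfg.label_noise`` and Gaussian observation noise is added to the
    features (and clamped to the referential ranges).  Fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _ranges(truth)
    M = truth.n_attributes
    N = truth.n_grades

    if cfg.scheme == "uniform":
        X = rng.uniform(lo, hi, size=(cfg.n_records, M))
        _, _, grades = assess_batch(X, truth)
    else:
        props = (
            np.full(N, 1.0 / N)
            if cfg.grade_proportions is None
            else np.asarray(cfg.grade_proportions, dtype=float)
        )
        if props.shape != (N,) or np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise ValueError("grade_proportions must be a length-N probability vector")
        targets = rng.choice(np.arange(1, N + 1), size=cfg.n_records, p=props)
        X = np.empty((cfg.n_records, M))
        grades = np.empty(cfg.n_records, dtype=int)
        pending = np.arange(cfg.n_records)
        for _ in range(cfg.max_rejection_rounds):
            draw = rng.uniform(lo, hi, size=(pending.size, M))
            _, _, g = assess_batch(draw, truth)
            hit = g == targets[pending]
            X[pending[hit]] = draw[hit]
            grades[pending[hit]] = g[hit]
            pending = pending[~hit]
            if pending.size == 0:
                break
        else:
            unreachable = sorted(set(targets[pending]))
            raise GradeUnreachableError(
                f"rejection sampling exhausted {cfg.max_rejection_rounds} rounds; "
                f"unreached target grades: {unreachable}"
            )

    if cfg.label_noise > 0:
        flip = rng.random(cfg.n_records) < cfg.label_noise
        # draw a uniformly random *other* grade for each flipped record
        offsets = rng.integers(1, N, size=cfg.n_records)
        grades = np.where(flip, (grades - 1 + offsets) % N + 1, grades)

    if cfg.feature_noise_scale > 0:
        sigma = cfg.feature_noise_scale * (hi - lo)
        X = np.clip(X + rng.normal(0.0, sigma, size=X.shape), lo, hi)

    return LabelledDataset(features=X, grades=grades)


def split(
    data: LabelledDataset, train_fraction: float, seed: int
) -> tuple[LabelledDataset, LabelledDataset]:
    """Shuffled disjoint train/test partition.

    Train size is ``floor(train_fraction * T)``; the remainder is the test
    set (2,000 records at 0.8 give the study's 1,600 / 400 design).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    T = len(data)
    n_train = int(train_fraction * T)
    if n_train == 0 or n_train == T:
        raise ValueError(f"split of {T} records at fraction {train_fraction} leaves an empty part")
    perm = np.random.default_rng(seed).permutation(T)
    return data.subset(np.sort(perm[:n_train])), data.subset(np.sort(perm[n_train:]))


def perturb_rulebase(truth: BeliefRuleBase, magnitude: float, seed: int) -> BeliefRuleBase:
    """Jitter all learnable parameters by +/- ``magnitude`` and re-project.

    Emulates an imperfect expert initialization for parameter-recovery
    experiments: uniform jitter on every belief degree, rule weight and
    attribute weight, then clipping to [0, 1] and scaling each rule's belief
    vector down to sum <= 1.  Magnitude 0 is the identity.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    rng = np.random.default_rng(seed)
    theta = truth.rule_weights + rng.uniform(-magnitude, magnitude, truth.n_rules)
    delta = truth.attribute_weights + rng.uniform(-magnitude, magnitude, truth.n_attributes)
    B = truth.belief_matrix + rng.uniform(
        -magnitude, magnitude, (truth.n_rules, truth.n_grades)
    )
    theta = np.clip(theta, 0.0, 1.0)
    delta = np.clip(delta, 0.0, 1.0)
    if np.max(delta) <= 0:
        delta = np.ones_like(delta)
    B = np.clip(B, 0.0, 1.0)
    sums = B.sum(axis=1, keepdims=True)
    B = np.where(sums > 1.0, B / np.maximum(sums, 1e-300), B)
    return truth.with_parameters(rule_weights=theta, attribute_weights=delta, beliefs=B)
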