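"""Constrained parameter learning for belief rule bases.

The learnable parameters are packed into a flat vector
``[theta_1..theta_L, delta_1..delta_M, beta_{1,1}..beta_{L,N}]`` (138 entries
for the 27-rule, 3-attribute, 4-grade upper-limb model) and fitted by
minimizing the mean squared error between the model's expected utility and
each record's target utility (the utility of its labelled grade), subject to

* box constraints ``0 <= theta_k, delta_i, beta_{j,k} <= 1``, and
* one linear inequality per rule, ``sum_j beta_{j,k} <= 1`` (rules may stay
  incomplete).

Optimization uses a sequential-quadratic-programming local method
(scipy's SLSQP) with finite-difference gradients — the same family as
MATLAB's ``fmincon`` that the procedure emulates.  Referential values and
grade utilities are fixed: they are not part of the parameter vector.

An accept-if-better guard makes training monotone: if the optimizer ends at
a worse objective than the (feasibility-repaired) initialization, the
initialization is returned instead, with the report saying so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core import BeliefRuleBase, assess_batch
from .simulate import LabelledDataset

__all__ = [
    "ParameterLayout",
    "TrainingConfig",
    "ObjectiveValue",
    "TrainingReport",
    "pack_parameters",
    "unpack_parameters",
    "repair_feasibility",
    "mse_objective",
    "train",
]


@dataclass(frozen=True)
class ParameterLayout:
    """Index map between a flat parameter vector and a rule base."""

    n_rules: int
    n_attributes: int
    n_grades: int

    @property
    def size(self) -> int:
        return self.n_rules + self.n_attributes + self.n_rules * self.n_grades

    @property
    def theta(self) -> slice:
        return slice(0, self.n_rules)

    @property
    def delta(self) -> slice:
        return slice(self.n_rules, self.n_rules + self.n_attributes)

    @property
    def beta(self) -> slice:
        return slice(self.n_rules + self.n_attributes, self.size)

    @classmethod
    def of(cls, brb: BeliefRuleBase) -> "ParameterLayout":
        return cls(brb.n_rules, brb.n_attributes, brb.n_grades)


def pack_parameters(brb: BeliefRuleBase) -> np.ndarray:
    """Flatten (theta, delta, beta) into one vector; inverse of unpack."""
    return np.concatenate(
        [brb.rule_weights, brb.attribute_weights, brb.belief_matrix.ravel()]
    )


def unpack_parameters(vec: np.ndarray, template: BeliefRuleBase) -> BeliefRuleBase:
    """Rebuild a rule base from a flat vector, using ``template`` for structure."""
    lay = ParameterLayout.of(template)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (lay.size,):
        raise ValueError(f"expected parameter vector of length {lay.size}, got {vec.shape}")
    return template.with_parameters(
        rule_weights=vec[lay.theta],
        attribute_weights=vec[lay.delta],
        beliefs=vec[lay.beta].reshape(lay.n_rules, lay.n_grades),
    )


def _project(vec: np.ndarray, lay: ParameterLayout) -> np.ndarray:
    """Project a raw vector onto the feasible set (boxes + per-rule sums)."""
    v = np.clip(vec, 0.0, 1.0)
    B = v[lay.beta].reshape(lay.n_rules, lay.n_grades)
    sums = B.sum(axis=1, keepdims=True)
    np.divide(B, sums, out=B, where=sums > 1.0)
    v[lay.beta] = B.ravel()
    delta = v[lay.delta]
    if np.max(delta) <= 0:  # all-zero attribute weights leave activation undefined
        v[lay.delta] = 1.0
    return v


def repair_feasibility(brb: BeliefRuleBase) -> BeliefRuleBase:
    """Clip parameters to their boxes and rescale over-complete rule beliefs."""
    lay = ParameterLayout.of(brb)
    return unpack_parameters(_project(pack_parameters(brb), lay), brb)


@dataclass(frozen=True)
class ObjectiveValue:
    """MSE and the per-record residuals it is the mean square of."""

    mse: float
    residuals: np.ndarray


def mse_objective(
    params: np.ndarray, data: LabelledDataset, template: BeliefRuleBase
) -> ObjectiveValue:
    """Mean squared utility error of a parameter vector on labelled data.

    ``(1/T) sum_i (yhat_i - y_i^r)^2`` where ``yhat_i`` is the model's
    expected utility for record i and ``y_i^r`` the utility of its true
    grade.  Out-of-bounds parameters are projected onto the feasible set
    before evaluation.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    lay = ParameterLayout.of(template)
    brb = unpack_parameters(_project(np.array(params, dtype=float), lay), template)
    _, utilities, _ = assess_batch(data.features, brb)
    residuals = utilities - data.target_utilities(template)
    return ObjectiveValue(mse=float(np.mean(residuals**2)), residuals=residuals)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings; the defaults suit the 138-parameter model.

    ``train_theta`` / ``train_delta`` / ``train_beta`` freeze individual
    parameter blocks at their initial values when False.  ``n_starts > 1``
    adds jittered restarts of the initialization (seeded) and keeps the best
    final objective.
    """

    max_iter: int = 500
    tol: float = 1e-6
    constraint_tol: float = 1e-6
    n_starts: int = 1
    seed: int = 0
    train_theta: bool = True
    train_delta: bool = True
    train_beta: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.constraint_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("max_iter and n_starts must be >= 1")


@dataclass(frozen=True)
class TrainingReport:
    """Outcome of one training run."""

    initial_mse: float
    final_mse: float
    n_iterations: int
    converged: bool
    message: str
    n_records: int
    used_fallback: bool = False  # True when the accept-if-better guard fired

    def to_dict(self) -> dict:
        return {
            "initial_mse": self.initial_mse,
            "final_mse": self.final_mse,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "message": self.message,
            "n_records": self.n_records,
            "used_fallback": self.used_fallback,
        }


def _optimize_from(
    x0: np.ndarray,
    free: np.ndarray,
    data: LabelledDataset,
    template: BeliefRuleBase,
    cfg: TrainingConfig,
):
    """One SLSQP run over the free coordinates; returns (vec, fun, result)."""
    lay = ParameterLayout.of(template)
    base = x0.copy()

    def full(z: np.ndarray) -> np.ndarray:
        v = base.copy()
        v[free] = z
        return v

    def fun(z: np.ndarray) -> float:
        return mse_objective(full(z), data, template).mse

    constraints = []
    if cfg.train_beta:

        def belief_sum_slack(z: np.ndarray) -> np.ndarray:
            v = full(z)
            B = v[lay.beta].reshape(lay.n_rules, lay.n_grades)
            return 1.0 - B.sum(axis=1)

        constraints.append({"type": "ineq", "fun": belief_sum_slack})

    res = minimize(
        fun,
        x0[free],
        method="SLSQP",
        bounds=[(0.0, 1.0)] * int(free.sum()),
        constraints=constraints,
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
    )
    vec = _project(full(res.x), lay)
    return vec, mse_objective(vec, data, template).mse, res


def train(
    init: BeliefRuleBase, data: LabelledDataset, cfg: TrainingConfig | None = None
) -> tuple[BeliefRuleBase, TrainingReport]:
    """Fit (theta, delta, beta) to labelled data by constrained MSE descent.

    The initialization is feasibility-repaired first; the returned rule base
    always satisfies the box and belief-sum constraints and never scores
    worse than the repaired initialization (accept-if-better guard).
    """
    if cfg is None:
        cfg = TrainingConfig()
    if not data.is_labelled:
        raise ValueError("training requires a labelled dataset")
    lay = ParameterLayout.of(init)
    x0 = _project(pack_parameters(init), lay)
    initial = mse_objective(x0, data, init).mse

    free = np.zeros(lay.size, dtype=bool)
    free[lay.theta] = cfg.train_theta
    free[lay.delta] = cfg.train_delta
    free[lay.beta] = cfg.train_beta
    if not free.any():
        raise ValueError("all parameter blocks are frozen; nothing to train")

    starts = [x0]
    if cfg.n_starts > 1:
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.n_starts - 1):
            jitter = np.where(free, rng.uniform(-0.1, 0.1, lay.size), 0.0)
            starts.append(_project(x0 + jitter, lay))

    best_vec, best_fun, best_res = None, np.inf, None
    for s in starts:
        vec, fun_val, res = _optimize_from(s, free, data, init, cfg)
        if fun_val < best_fun:
            best_vec, best_fun, best_res = vec, fun_val, res

    used_fallback = best_fun > initial + cfg.constraint_tol
    if used_fallback:
        best_vec, best_fun = x0, initial
    trained = unpack_parameters(best_vec, init)
    report = TrainingReport(
        initial_mse=initial,
        final_mse=min(best_fun, initial) if used_fallback else best_fun,
        n_iterations=int(getattr(best_res, "nit", 0)),
        converged=bool(getattr(best_res, "success", False)),
        message=str(getattr(best_res, "message", "")),
        n_records=len(data),
        used_fallback=used_fallback,
    )
    return trained, report
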