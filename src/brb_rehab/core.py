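"""Belief rule base (BRB) model and evidential-reasoning (ER) inference.

A BRB extends IF-THEN rule systems by attaching to every rule a *belief
distribution* over outcome grades instead of a single conclusion.  Inference
for an input feature vector runs in four stages:

1. **Matching degrees** — each attribute value is matched against the
   attribute's ordered referential values by linear interpolation between the
   two bracketing values, yielding degrees in [0, 1] that sum to 1 per
   attribute.
2. **Activation weights** — each rule k receives
   ``w_k = theta_k * prod_i a_i(k)**dbar_i`` normalized over rules, where
   ``theta_k`` is the rule weight, ``a_i(k)`` the matching degree of the
   rule's referential value for attribute i, and ``dbar_i`` the attribute
   weight normalized by its maximum.
3. **ER aggregation** — the activated rules' belief distributions are fused
   with the analytic evidential-reasoning formula (a closed form of the
   recursive Dempster-Shafer style combination of weighted, possibly
   incomplete belief distributions).
4. **Expected utility and grade** — the aggregated beliefs are collapsed to
   a scalar ``sum_j u(D_j) * beta_j`` and mapped to the nearest grade
   utility (ties break toward the lower grade).

The default upper-limb rehabilitation model uses three antecedent
attributes — active resistance torque of the upper limb (ARTUL),
rehabilitation training time (RTT) and mean amplitude of muscle strength
(MAMS), three referential values each — and four health grades I-IV with
utilities {1, 2, 3, 4}, giving a full grid of 27 rules.

Scalar operations mirror the conceptual pipeline one input at a time;
:func:`assess_batch` is the vectorized equivalent used by training,
simulation and evaluation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BELIEF_SUM_TOL",
    "AttributeSpec",
    "Rule",
    "BeliefRuleBase",
    "MatchingProfile",
    "ActivationProfile",
    "AssessmentResult",
    "NoRuleActivatedError",
    "compute_matching_degrees",
    "compute_activation_weights",
    "aggregate_er",
    "expected_utility",
    "classify",
    "assess",
    "assess_batch",
    "full_grid_rulebase",
]

#: Absolute tolerance for all belief-sum checks.
BELIEF_SUM_TOL = 1e-9


class NoRuleActivatedError(ValueError):
    """Raised when every rule's activation numerator is zero.

    This happens when all rule weights are zero, or when (pathologically)
    every rule has a zero matching-degree factor; silent NaN propagation is
    never acceptable in a clinical scoring path.
    """


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {values!r}")
    return arr


@dataclass(frozen=True)
class AttributeSpec:
    """One antecedent attribute with its ordered referential values.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"ARTUL"``.
    labels:
        Ordered semantic labels, e.g. ``("S", "N", "B")``.
    ref_values:
        Strictly increasing quantized referential values, in attribute
        units, one per label.
    """

    name: str
    labels: tuple[str, ...]
    ref_values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "ref_values", tuple(float(v) for v in self.ref_values))
        if len(self.labels) != len(self.ref_values):
            raise ValueError(
                f"attribute {self.name!r}: {len(self.labels)} labels but "
                f"{len(self.ref_values)} referential values"
            )
        if len(self.ref_values) < 2:
            raise ValueError(f"attribute {self.name!r}: need at least 2 referential values")
        if not all(a < b for a, b in itertools.pairwise(self.ref_values)):
            raise ValueError(
                f"attribute {self.name!r}: referential values must be strictly "
                f"increasing, got {self.ref_values}"
            )

    @property
    def n_refs(self) -> int:
        return len(self.ref_values)


def validate_belief(beliefs, n_grades: int, *, context: str = "belief") -> np.ndarray:
    """Validate a belief distribution: entries in [0,1], sum <= 1 + tol."""
    arr = _as_float_array(beliefs, context)
    if arr.ndim != 1 or arr.size != n_grades:
        raise ValueError(f"{context}: expected {n_grades} belief degrees, got shape {arr.shape}")
    if np.any(arr < -BELIEF_SUM_TOL) or np.any(arr > 1 + BELIEF_SUM_TOL):
        raise ValueError(f"{context}: belief degrees must lie in [0, 1], got {arr}")
    total = float(arr.sum())
    if total > 1 + BELIEF_SUM_TOL:
        raise ValueError(f"{context}: belief degrees sum to {total:.12g} > 1")
    return arr


@dataclass(frozen=True)
class Rule:
    """One belief rule: antecedent referential-value indices, weight, beliefs.

    ``antecedent[i]`` indexes into attribute i's referential values; ``weight``
    is the rule weight theta in [0, 1]; ``belief`` holds one degree per grade
    and may sum to less than 1 (an *incomplete* rule).
    """

    antecedent: tuple[int, ...]
    weight: float
    belief: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", tuple(int(i) for i in self.antecedent))
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"rule weight must lie in [0, 1], got {self.weight}")
        b = _as_float_array(self.belief, "rule belief")
        object.__setattr__(self, "belief", b)

    @property
    def is_complete(self) -> bool:
        return math.isclose(float(self.belief.sum()), 1.0, abs_tol=BELIEF_SUM_TOL)


@dataclass(frozen=True)
class BeliefRuleBase:
    """A complete belief rule base over a full grid of antecedent combinations.

    Attributes
    ----------
    attributes:
        The M antecedent attributes.
    attribute_weights:
        delta_1..delta_M in [0, 1]; normalized internally by their maximum
        when computing activation weights.
    rules:
        Exactly one rule per point of the referential-value grid, i.e.
        ``L = prod_i J_i`` rules (27 for the 3x3x3 rehabilitation model).
    grade_labels:
        Names of the N outcome grades (``("I", "II", "III", "IV")``).
    grade_utilities:
        Strictly increasing utility u(D_j) per grade ({1, 2, 3, 4}).
    """

    attributes: tuple[AttributeSpec, ...]
    attribute_weights: np.ndarray
    rules: tuple[Rule, ...]
    grade_labels: tuple[str, ...]
    grade_utilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(self, "grade_labels", tuple(str(g) for g in self.grade_labels))
        dw = _as_float_array(self.attribute_weights, "attribute_weights")
        gu = _as_float_array(self.grade_utilities, "grade_utilities")
        object.__setattr__(self, "attribute_weights", dw)
        object.__setattr__(self, "grade_utilities", gu)

        M = len(self.attributes)
        if dw.shape != (M,):
            raise ValueError(f"expected {M} attribute weights, got shape {dw.shape}")
        if np.any(dw < 0) or np.any(dw > 1):
            raise ValueError(f"attribute weights must lie in [0, 1], got {dw}")
        if np.max(dw) <= 0:
            raise ValueError("at least one attribute weight must be positive")
        N = len(self.grade_labels)
        if gu.shape != (N,):
            raise ValueError(f"expected {N} grade utilities, got shape {gu.shape}")
        if not np.all(np.diff(gu) > 0):
            raise ValueError(f"grade utilities must be strictly increasing, got {gu}")

        grid_size = int(np.prod([a.n_refs for a in self.attributes]))
        if len(self.rules) != grid_size:
            raise ValueError(
                f"expected {grid_size} rules (full referential grid), got {len(self.rules)}"
            )
        seen: set[tuple[int, ...]] = set()
        for k, rule in enumerate(self.rules, start=1):
            if len(rule.antecedent) != M:
                raise ValueError(f"rule {k}: antecedent length {len(rule.antecedent)} != {M}")
            for i, (idx, attr) in enumerate(zip(rule.antecedent, self.attributes)):
                if not 0 <= idx < attr.n_refs:
                    raise ValueError(
                        f"rule {k}: antecedent index {idx} invalid for attribute "
                        f"{attr.name!r} with {attr.n_refs} referential values"
                    )
            if rule.antecedent in seen:
                raise ValueError(f"rule {k}: duplicate antecedent {rule.antecedent}")
            seen.add(rule.antecedent)
            validate_belief(rule.belief, N, context=f"rule {k}")

    # -- convenience views used by the vectorized paths -------------------

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def n_grades(self) -> int:
        return len(self.grade_labels)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def rule_weights(self) -> np.ndarray:
        """theta_1..theta_L as an (L,) array."""
        return np.array([r.weight for r in self.rules])

    @property
    def belief_matrix(self) -> np.ndarray:
        """Rule consequent beliefs as an (L, N) array."""
        return np.array([r.belief for r in self.rules])

    @property
    def antecedent_matrix(self) -> np.ndarray:
        """Rule antecedent referential-value indices as an (L, M) int array."""
        return np.array([r.antecedent for r in self.rules], dtype=int)

    @property
    def normalized_attribute_weights(self) -> np.ndarray:
        """dbar_i = delta_i / max_j delta_j."""
        dw = self.attribute_weights
        return dw / np.max(dw)

    def rule_index(self, antecedent: tuple[int, ...]) -> int:
        """Position of the rule with the given antecedent indices."""
        ant = tuple(int(i) for i in antecedent)
        for k, rule in enumerate(self.rules):
            if rule.antecedent == ant:
                return k
        raise KeyError(f"no rule with antecedent {antecedent}")

    def with_parameters(
        self,
        *,
        rule_weights: np.ndarray | None = None,
        attribute_weights: np.ndarray | None = None,
        beliefs: np.ndarray | None = None,
    ) -> "BeliefRuleBase":
        """Copy of this rule base with some parameter blocks replaced."""
        theta = self.rule_weights if rule_weights is None else np.asarray(rule_weights, float)
        delta = (
            self.attribute_weights
            if attribute_weights is None
            else np.asarray(attribute_weights, float)
        )
        B = self.belief_matrix if beliefs is None else np.asarray(beliefs, float)
        rules = tuple(
            Rule(antecedent=r.antecedent, weight=float(theta[k]), belief=B[k])
            for k, r in enumerate(self.rules)
        )
        return replace(self, attribute_weights=delta, rules=rules)


def full_grid_rulebase(
    attributes: list[AttributeSpec] | tuple[AttributeSpec, ...],
    beliefs: np.ndarray,
    *,
    rule_weights: np.ndarray | None = None,
    attribute_weights: np.ndarray | None = None,
    grade_labels: tuple[str, ...] = ("I", "II", "III", "IV"),
    grade_utilities=(1.0, 2.0, 3.0, 4.0),
) -> BeliefRuleBase:
    """Build a BRB over the full referential grid in lexicographic order.

    Rule order follows ``itertools.product`` over attribute referential
    indices — the last attribute varies fastest, matching the conventional
    tabular listing of expert rule bases (rule 1 = all-lowest, rule L =
    all-highest).
    """
    attributes = tuple(attributes)
    grid = list(itertools.product(*(range(a.n_refs) for a in attributes)))
    beliefs = np.asarray(beliefs, dtype=float)
    if beliefs.shape != (len(grid), len(grade_labels)):
        raise ValueError(
            f"beliefs must have shape {(len(grid), len(grade_labels))}, got {beliefs.shape}"
        )
    theta = np.ones(len(grid)) if rule_weights is None else np.asarray(rule_weights, float)
    delta = (
        np.ones(len(attributes))
        if attribute_weights is None
        else np.asarray(attribute_weights, float)
    )
    rules = tuple(
        Rule(antecedent=ant, weight=float(theta[k]), belief=beliefs[k])
        for k, ant in enumerate(grid)
    )
    return BeliefRuleBase(
        attributes=attributes,
        attribute_weights=delta,
        rules=rules,
        grade_labels=grade_labels,
        grade_utilities=np.asarray(grade_utilities, dtype=float),
    )


# ---------------------------------------------------------------------------
# Stage 1: matching degrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchingProfile:
    """Per-attribute matching degrees against each referential value.

    ``degrees[i]`` is a vector over attribute i's referential values; entries
    lie in [0, 1], sum to 1, and at most two consecutive entries are nonzero
    (the input falls between two adjacent referential values).
    """

    degrees: tuple[np.ndarray, ...]


def _matching_degrees_1d(x: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Piecewise-linear matching of values ``x`` (T,) against refs (J,) -> (T, J).

    Inputs outside [refs[0], refs[-1]] are clamped to the nearest boundary
    referential value (degree 1 there), preserving the sum-to-1 invariant.
    """
    T, J = x.shape[0], refs.shape[0]
    xc = np.clip(x, refs[0], refs[-1])
    # interval index l with refs[l] <= xc <= refs[l+1]
    l = np.clip(np.searchsorted(refs, xc, side="right") - 1, 0, J - 2)
    upper = refs[l + 1]
    lower = refs[l]
    a_low = (upper - xc) / (upper - lower)
    out = np.zeros((T, J))
    rows = np.arange(T)
    out[rows, l] = a_low
    out[rows, l + 1] = 1.0 - a_low
    return out


def compute_matching_degrees(
    x, attrs: list[AttributeSpec] | tuple[AttributeSpec, ...]
) -> MatchingProfile:
    """Match one feature vector against each attribute's referential values.

    For ``x_i`` in ``[A_i^l, A_i^{l+1}]`` the degree at l is
    ``(A_i^{l+1} - x_i) / (A_i^{l+1} - A_i^l)`` and the degree at l+1 its
    complement; all other degrees are zero.  Out-of-range inputs are clamped
    to the nearest boundary referential value.
    """
    xv = _as_float_array(x, "feature vector")
    if xv.ndim != 1 or xv.size != len(attrs):
        raise ValueError(f"expected {len(attrs)} feature values, got shape {xv.shape}")
    degrees = tuple(
        _matching_degrees_1d(xv[i : i + 1], np.asarray(a.ref_values))[0]
        for i, a in enumerate(attrs)
    )
    return MatchingProfile(degrees=degrees)


# ---------------------------------------------------------------------------
# Stage 2: activation weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationProfile:
    """Normalized rule activation weights w_1..w_L (sum to 1)."""

    weights: np.ndarray


def compute_activation_weights(m: MatchingProfile, brb: BeliefRuleBase) -> ActivationProfile:
    """Combine rule weights and matching degrees into normalized activations.

    ``w_k = theta_k * prod_i a_i(k)**dbar_i`` normalized over all rules, with
    ``dbar_i = delta_i / max_j delta_j``.  A zero matching degree annihilates
    a rule's numerator whenever the attribute carries positive normalized
    weight (the ``0**0 = 1`` convention is deliberately *not* used for
    positive weights; a genuinely zero-weight attribute contributes a unit
    factor, as x**0 does).
    """
    if len(m.degrees) != brb.n_attributes:
        raise ValueError(
            f"matching profile has {len(m.degrees)} attributes, rule base has {brb.n_attributes}"
        )
    dbar = brb.normalized_attribute_weights
    ant = brb.antecedent_matrix  # (L, M)
    numer = brb.rule_weights.copy()
    for i in range(brb.n_attributes):
        numer *= m.degrees[i][ant[:, i]] ** dbar[i]
    total = float(numer.sum())
    if total <= 0.0:
        raise NoRuleActivatedError(
            "no rule activated: every rule's weighted matching product is zero"
        )
    return ActivationProfile(weights=numer / total)


# ---------------------------------------------------------------------------
# Stage 3: analytic ER aggregation
# ---------------------------------------------------------------------------


def _aggregate_er_batch(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Analytic ER fusion for a batch of activation profiles.

    Parameters
    ----------
    W:
        (T, L) activation weights, each row summing to 1.
    B:
        (L, N) rule consequent beliefs.

    Returns
    -------
    (T, N) aggregated belief distributions.

    Notes
    -----
    With ``s_k = sum_j beta_{j,k}``, the closed form is::

        P_j   = prod_k (w_k beta_{j,k} + 1 - w_k s_k)
        P_D   = prod_k (1 - w_k s_k)
        P_w   = prod_k (1 - w_k)
        mu    = 1 / (sum_j P_j - (N-1) P_D)
        beta_j = mu (P_j - P_D) / (1 - mu P_w)

    The normalizer uses N-1 (number of grades minus one), the standard ER
    regulator; a one-hot activation then reproduces that rule's beliefs
    exactly, including the degenerate ``P_w = 0`` case where the denominator
    is simply 1.
    """
    N = B.shape[1]
    s = B.sum(axis=1)  # (L,)
    ws = W * s  # (T, L)
    factors = W[:, :, None] * B[None, :, :] + (1.0 - ws)[:, :, None]  # (T, L, N)
    P = np.prod(factors, axis=1)  # (T, N)
    P_D = np.prod(1.0 - ws, axis=1)  # (T,)
    P_w = np.prod(1.0 - W, axis=1)  # (T,)
    mu = 1.0 / (P.sum(axis=1) - (N - 1) * P_D)
    denom = 1.0 - mu * P_w
    return mu[:, None] * (P - P_D[:, None]) / denom[:, None]


def aggregate_er(w: ActivationProfile, brb: BeliefRuleBase) -> np.ndarray:
    """Fuse the activated rules' beliefs with the analytic ER formula.

    Returns the aggregated belief distribution over the N grades.  If every
    rule with positive activation is complete, the result sums to 1 (within
    :data:`BELIEF_SUM_TOL`).
    """
    W = _as_float_array(w.weights, "activation weights")
    if W.shape != (brb.n_rules,):
        raise ValueError(f"expected {brb.n_rules} activation weights, got shape {W.shape}")
    if np.any(W < -BELIEF_SUM_TOL) or not math.isclose(float(W.sum()), 1.0, abs_tol=1e-9):
        raise ValueError(f"activation weights must be nonnegative and sum to 1, got sum {W.sum()}")
    return _aggregate_er_batch(W[None, :], brb.belief_matrix)[0]


# ---------------------------------------------------------------------------
# Stage 4: expected utility and grade
# ---------------------------------------------------------------------------


def expected_utility(b, brb: BeliefRuleBase, *, renormalize: bool = False) -> float:
    """Collapse an aggregated belief distribution to ``sum_j u(D_j) beta_j``.

    By default the belief mass is used as-is, so an incomplete distribution
    yields a conservatively shrunken utility.  ``renormalize=True`` divides
    by the total belief mass first.
    """
    arr = _as_float_array(b, "belief distribution")
    if arr.shape != (brb.n_grades,):
        raise ValueError(
            f"belief distribution has {arr.size} entries, rule base has {brb.n_grades} grades"
        )
    total = float(arr.sum())
    if renormalize and total > 0:
        arr = arr / total
    return float(arr @ brb.grade_utilities)


def classify(utility: float, brb: BeliefRuleBase) -> int:
    """Map a continuous utility to the nearest grade (1-based index).

    Ties break toward the lower (healthier) grade; utilities outside the
    grade-utility range snap to the nearest end.
    """
    u = brb.grade_utilities
    return int(np.argmin(np.abs(u - float(utility)))) + 1


@dataclass(frozen=True)
class AssessmentResult:
    """Full output of one inference pass, kept for traceability.

    ``grade`` is the 1-based index into the rule base's grade labels;
    ``belief`` the aggregated distribution; ``utility`` the expected utility;
    ``activation`` the rule activation profile that produced it.
    """

    belief: np.ndarray
    utility: float
    grade: int
    activation: ActivationProfile

    @property
    def grade_index(self) -> int:
        return self.grade


def assess(x, brb: BeliefRuleBase, *, renormalize: bool = False) -> AssessmentResult:
    """Run the full inference pass for one feature vector."""
    m = compute_matching_degrees(x, brb.attributes)
    w = compute_activation_weights(m, brb)
    b = aggregate_er(w, brb)
    u = expected_utility(b, brb, renormalize=renormalize)
    return AssessmentResult(belief=b, utility=u, grade=classify(u, brb), activation=w)


# ---------------------------------------------------------------------------
# Vectorized batch inference
# ---------------------------------------------------------------------------


def assess_batch(
    X, brb: BeliefRuleBase, *, renormalize: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized inference over a feature matrix.

    Parameters
    ----------
    X:
        (T, M) feature matrix, one row per record.
    brb:
        The rule base.
    renormalize:
        Divide aggregated beliefs by their total mass before computing
        utilities.

    Returns
    -------
    beliefs : (T, N) aggregated belief distributions
    utilities : (T,) expected utilities
    grades : (T,) 1-based grade indices

    Equivalent to calling :func:`assess` row by row, but a single numpy
    pipeline; this is the path the trainer's objective function hammers.
    """
    X = _as_float_array(X, "feature matrix")
    if X.ndim != 2 or X.shape[1] != brb.n_attributes:
        raise ValueError(f"expected shape (T, {brb.n_attributes}), got {X.shape}")
    T = X.shape[0]
    dbar = brb.normalized_attribute_weights
    ant = brb.antecedent_matrix
    numer = np.broadcast_to(brb.rule_weights, (T, brb.n_rules)).copy()
    for i, attr in enumerate(brb.attributes):
        mi = _matching_degrees_1d(X[:, i], np.asarray(attr.ref_values))  # (T, J_i)
        numer *= mi[:, ant[:, i]] ** dbar[i]
    totals = numer.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise NoRuleActivatedError(
            f"no rule activated for record {bad}: weighted matching products are all zero"
        )
    W = numer / totals[:, None]
    beliefs = _aggregate_er_batch(W, brb.belief_matrix)
    mass = beliefs.sum(axis=1)
    if renormalize:
        safe = np.where(mass > 0, mass, 1.0)
        utilities = (beliefs / safe[:, None]) @ brb.grade_utilities
    else:
        utilities = beliefs @ brb.grade_utilities
    grades = np.argmin(np.abs(brb.grade_utilities[None, :] - utilities[:, None]), axis=1) + 1
    return beliefs, utilities, grades
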