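"""Unit and property tests for the BRB inference pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from brb_rehab import (
    ActivationProfile,
    AttributeSpec,
    NoRuleActivatedError,
    aggregate_er,
    assess,
    assess_batch,
    classify,
    compute_activation_weights,
    compute_matching_degrees,
    expected_utility,
    full_grid_rulebase,
)
from conftest import random_small_instance
from er_oracle import combine_er_recursive


# ---------------------------------------------------------------------------
# matching degrees
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value, attr_index, expected",
    [
        (4.0, 0, [1.0, 0.0, 0.0]),  # exactly on a referential value
        (6.0, 0, [0.5, 0.5, 0.0]),  # midpoint of ARTUL [4, 8]
        (13.0, 1, [0.0, 0.4, 0.6]),  # RTT between 10 and 15
        (20.0, 2, [0.0, 0.0, 1.0]),  # MAMS above range: clamped to the top
        (-3.0, 0, [1.0, 0.0, 0.0]),  # below range: clamped to the bottom
    ],
)
def test_matching_degree_interpolation(expert_brb, value, attr_index, expected):
    """Linear interpolation between adjacent referential values, clamped outside."""
    x = [a.ref_values[0] for a in expert_brb.attributes]
    x[attr_index] = value
    profile = compute_matching_degrees(x, expert_brb.attributes)
    np.testing.assert_allclose(profile.degrees[attr_index], expected, atol=1e-12)


def test_matching_degrees_reject_bad_input(expert_brb):
    with pytest.raises(ValueError):
        compute_matching_degrees([1.0, 2.0], expert_brb.attributes)
    with pytest.raises(ValueError):
        compute_matching_degrees([np.nan, 5.0, 5.0], expert_brb.attributes)


@given(
    x=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
    offsets=st.lists(st.floats(0.5, 10), min_size=6, max_size=6),
)
def test_matching_degrees_sum_to_one(x, offsets):
    """Per-attribute degrees always sum to 1 and have <= 2 nonzero entries."""
    attrs = [
        AttributeSpec(
            name=f"a{i}",
            labels=("lo", "mid", "hi"),
            ref_values=tuple(np.cumsum([0.0, offsets[2 * i], offsets[2 * i + 1]]) - 5.0),
        )
        for i in range(3)
    ]
    profile = compute_matching_degrees(x, attrs)
    for d in profile.degrees:
        assert np.all(d >= 0) and np.all(d <= 1)
        assert np.isclose(d.sum(), 1.0, atol=1e-9)
        nz = np.flatnonzero(d > 0)
        assert nz.size <= 2 and (nz.size < 2 or nz[1] - nz[0] == 1)


# ---------------------------------------------------------------------------
# activation weights
# ---------------------------------------------------------------------------


def test_activation_one_hot_at_grid_point(expert_brb):
    """A grid-corner input activates exactly its rule."""
    profile = compute_matching_degrees([4, 5, 5], expert_brb.attributes)
    w = compute_activation_weights(profile, expert_brb).weights
    k = expert_brb.rule_index((0, 0, 0))
    expected = np.zeros(expert_brb.n_rules)
    expected[k] = 1.0
    np.testing.assert_allclose(w, expected, atol=1e-12)


def test_activation_splits_between_adjacent_rules(expert_brb):
    """ARTUL midway between S and N activates (S,S,S) and (N,S,S) equally."""
    profile = compute_matching_degrees([6, 5, 5], expert_brb.attributes)
    w = compute_activation_weights(profile, expert_brb).weights
    k1 = expert_brb.rule_index((0, 0, 0))
    k2 = expert_brb.rule_index((1, 0, 0))
    assert w[k1] == pytest.approx(0.5) and w[k2] == pytest.approx(0.5)
    assert w.sum() == pytest.approx(1.0)


def test_activation_weights_rule_weights(expert_brb):
    """Unequal rule weights tilt the activation split: (0.2, 0.6) -> (0.25, 0.75)."""
    theta = np.zeros(expert_brb.n_rules)
    k1 = expert_brb.rule_index((0, 0, 0))
    k2 = expert_brb.rule_index((1, 0, 0))
    theta[k1], theta[k2] = 0.2, 0.6
    brb = expert_brb.with_parameters(rule_weights=theta)
    profile = compute_matching_degrees([6, 5, 5], brb.attributes)
    w = compute_activation_weights(profile, brb).weights
    assert w[k1] == pytest.approx(0.25) and w[k2] == pytest.approx(0.75)


def test_all_zero_rule_weights_raise(expert_brb):
    brb = expert_brb.with_parameters(rule_weights=np.zeros(expert_brb.n_rules))
    profile = compute_matching_degrees([6, 7, 8], brb.attributes)
    with pytest.raises(NoRuleActivatedError):
        compute_activation_weights(profile, brb)


@given(
    x=st.lists(st.floats(0, 20), min_size=3, max_size=3),
    theta_seed=st.integers(0, 10_000),
)
def test_activation_weights_normalized(expert_brb, x, theta_seed):
    """Activation weights lie in [0, 1] and sum to 1 for any in-range input."""
    rng = np.random.default_rng(theta_seed)
    brb = expert_brb.with_parameters(
        rule_weights=rng.uniform(0.1, 1.0, expert_brb.n_rules),
        attribute_weights=rng.uniform(0.1, 1.0, expert_brb.n_attributes),
    )
    profile = compute_matching_degrees(x, brb.attributes)
    w = compute_activation_weights(profile, brb).weights
    assert np.all(w >= 0) and np.all(w <= 1 + 1e-12)
    assert np.isclose(w.sum(), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# ER aggregation
# ---------------------------------------------------------------------------


def _uniform_brb(beliefs):
    """Full-grid single-attribute rule base carrying the given (L, N) beliefs."""
    beliefs = np.asarray(beliefs, dtype=float)
    L, N = beliefs.shape
    attr = AttributeSpec("x", tuple(f"v{i}" for i in range(L)), tuple(range(L)))
    return full_grid_rulebase(
        [attr],
        beliefs,
        grade_labels=tuple(f"D{j}" for j in range(N)),
        grade_utilities=np.arange(1.0, N + 1.0),
    )


def test_aggregate_one_hot_identity():
    """A one-hot activation returns that rule's belief exactly."""
    brb = _uniform_brb([[1, 0, 0, 0], [0, 0, 0, 1]])
    out = aggregate_er(ActivationProfile(np.array([1.0, 0.0])), brb)
    np.testing.assert_allclose(out, [1, 0, 0, 0], atol=1e-12)


def test_aggregate_consensus_degenerate():
    """Two rules agreeing on a point distribution reproduce it."""
    brb = _uniform_brb([[1, 0, 0, 0], [1, 0, 0, 0]])
    out = aggregate_er(ActivationProfile(np.array([0.5, 0.5])), brb)
    np.testing.assert_allclose(out, [1, 0, 0, 0], atol=1e-12)


def test_aggregate_symmetric_conflict():
    """Equal-weight point beliefs on two grades fuse to a 50/50 split."""
    brb = _uniform_brb([[1, 0, 0, 0], [0, 1, 0, 0]])
    out = aggregate_er(ActivationProfile(np.array([0.5, 0.5])), brb)
    np.testing.assert_allclose(out, [0.5, 0.5, 0, 0], atol=1e-10)
    oracle = combine_er_recursive(np.array([0.5, 0.5]), brb.belief_matrix)
    np.testing.assert_allclose(out, oracle, atol=1e-10)


def test_aggregate_rejects_unnormalized_weights():
    brb = _uniform_brb([[1, 0, 0, 0], [0, 1, 0, 0]])
    with pytest.raises(ValueError):
        aggregate_er(ActivationProfile(np.array([0.5, 0.6])), brb)


@pytest.mark.parametrize("seed", range(50))
def test_aggregate_matches_recursive_oracle(seed):
    """Analytic ER equals the recursive two-source combination, 1e-10."""
    w, beliefs, brb = random_small_instance(np.random.default_rng(seed))
    out = aggregate_er(ActivationProfile(w), brb)
    oracle = combine_er_recursive(w, beliefs)
    np.testing.assert_allclose(out, oracle, atol=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_aggregate_permutation_invariance(seed):
    """Permuting rule order (with weights) leaves the fused belief unchanged."""
    rng = np.random.default_rng(seed)
    w, beliefs, _ = random_small_instance(rng)
    perm = rng.permutation(len(w))
    out = combine_er_recursive(w, beliefs)  # reference on original order
    brb_p = _uniform_brb(beliefs[perm])
    out_p = aggregate_er(ActivationProfile(w[perm]), brb_p)
    np.testing.assert_allclose(out_p, out, atol=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_aggregate_complete_rules_conserve_mass(seed):
    """When all rules are complete the fused belief sums to 1."""
    rng = np.random.default_rng(seed)
    L, N = int(rng.integers(2, 6)), int(rng.integers(2, 6))
    beliefs = rng.dirichlet(np.ones(N), size=L)
    w = rng.dirichlet(np.ones(L))
    out = aggregate_er(ActivationProfile(w), _uniform_brb(beliefs))
    assert np.all(out >= -1e-12) and np.isclose(out.sum(), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# utility and grade
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "beliefs, expected",
    [([1, 0, 0, 0], 1.0), ([0, 0, 0, 1], 4.0), ([0.5, 0.5, 0, 0], 1.5)],
)
def test_expected_utility(expert_brb, beliefs, expected):
    assert expected_utility(np.array(beliefs), expert_brb) == pytest.approx(expected)


def test_expected_utility_renormalizes_incomplete_mass(expert_brb):
    b = np.array([0.4, 0.4, 0.0, 0.0])  # mass 0.8
    assert expected_utility(b, expert_brb) == pytest.approx(1.2)
    assert expected_utility(b, expert_brb, renormalize=True) == pytest.approx(1.5)


def test_expected_utility_dimension_mismatch(expert_brb):
    with pytest.raises(ValueError):
        expected_utility(np.array([1.0, 0.0]), expert_brb)


@pytest.mark.parametrize(
    "utility, expected_grade",
    [(1.0, 1), (2.49, 2), (2.5, 2), (2.51, 3), (4.0, 4), (0.2, 1), (4.3, 4)],
)
def test_classify_nearest_utility_tie_low(expert_brb, utility, expected_grade):
    """Nearest-utility grading; exact midpoints go to the lower grade."""
    assert classify(utility, expert_brb) == expected_grade


# ---------------------------------------------------------------------------
# full assessment
# ---------------------------------------------------------------------------


def test_assess_grid_corners(expert_brb):
    """Grid-corner inputs reproduce the expert table's belief rows exactly."""
    r = assess([4, 5, 5], expert_brb)
    np.testing.assert_allclose(r.belief, [1, 0, 0, 0], atol=1e-12)
    assert r.utility == pytest.approx(1.0) and r.grade == 1
    r = assess([12, 15, 11], expert_brb)
    np.testing.assert_allclose(r.belief, [0, 0, 0, 1], atol=1e-12)
    assert r.utility == pytest.approx(4.0) and r.grade == 4


def test_assess_trained_corner_literal_utility(trained_brb):
    """The trained base's first rule fires alone; its (incomplete) beliefs
    give utility 0.835*1 + 0.15*2 + 0.013*3 = 1.174 without renormalization."""
    r = assess([4, 5, 5], trained_brb)
    np.testing.assert_allclose(r.belief, [0.835, 0.15, 0.013, 0.0], atol=1e-12)
    assert r.utility == pytest.approx(1.174)
    assert r.grade == 1


@pytest.mark.parametrize("seed", range(10))
def test_assess_batch_matches_scalar_path(expert_brb, seed):
    """The vectorized pipeline is exactly the scalar pipeline per row."""
    rng = np.random.default_rng(seed)
    X = rng.uniform([4, 5, 5], [12, 15, 11], size=(8, 3))
    beliefs, utilities, grades = assess_batch(X, expert_brb)
    for t in range(X.shape[0]):
        r = assess(X[t], expert_brb)
        np.testing.assert_allclose(beliefs[t], r.belief, atol=1e-12)
        assert utilities[t] == pytest.approx(r.utility)
        assert grades[t] == r.grade


@given(
    x=st.lists(st.floats(0, 20), min_size=3, max_size=3),
)
def test_assess_utility_within_grade_bounds(expert_brb, x):
    """With complete rules, expected utility stays within [u(D_1), u(D_N)]."""
    r = assess(x, expert_brb)
    u = expert_brb.grade_utilities
    assert u[0] - 1e-9 <= r.utility <= u[-1] + 1e-9
    assert np.isclose(r.belief.sum(), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# rule-base construction invariants
# ---------------------------------------------------------------------------


def test_full_grid_order_and_size(expert_brb):
    """27 rules in lexicographic order, last attribute fastest."""
    expected = list(itertools.product(range(3), repeat=3))
    assert [r.antecedent for r in expert_brb.rules] == expected


def test_rulebase_rejects_duplicate_and_overfull_rules(expert_brb):
    beliefs = expert_brb.belief_matrix.copy()
    beliefs[3] = [0.7, 0.6, 0.0, 0.0]  # sums to 1.3
    with pytest.raises(ValueError, match="rule 4"):
        expert_brb.with_parameters(beliefs=beliefs)


def test_attribute_spec_requires_increasing_refs():
    with pytest.raises(ValueError):
        AttributeSpec("a", ("x", "y"), (2.0, 2.0))
    with pytest.raises(ValueError):
        AttributeSpec("a", ("x", "y", "z"), (1.0, 2.0))
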