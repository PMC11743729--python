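import numpy as np
import pytest
from hypothesis import settings

from brb_rehab import (
    AttributeSpec,
    full_grid_rulebase,
    initial_expert_rulebase,
    reference_trained_rulebase,
)

settings.register_profile("suite", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def expert_brb():
    """The packaged initial expert rule base (27 rules, theta = delta = 1)."""
    return initial_expert_rulebase()


@pytest.fixture(scope="session")
def trained_brb():
    """The packaged reference trained rule base (default truth model)."""
    return reference_trained_rulebase()


def random_small_instance(rng: np.random.Generator):
    """A random ER fusion instance: L in 2..5 rules, N in 2..5 grades.

    Returns (weights, beliefs, brb) where brb is a single-attribute
    full-grid rule base whose L rules carry the beliefs, so the instance can
    be fed both to the package's aggregation and to the recursive oracle.
    """
    L = int(rng.integers(2, 6))
    N = int(rng.integers(2, 6))
    w = rng.dirichlet(np.ones(L))
    beliefs = rng.dirichlet(np.ones(N + 1), size=L)[:, :N]  # rows sum to <= 1
    # occasionally make rules complete
    complete = rng.random(L) < 0.5
    beliefs[complete] /= beliefs[complete].sum(axis=1, keepdims=True)
    attr = AttributeSpec(
        name="x", labels=tuple(f"v{i}" for i in range(L)), ref_values=tuple(range(L))
    )
    brb = full_grid_rulebase(
        [attr],
        beliefs,
        grade_labels=tuple(f"D{j}" for j in range(N)),
        grade_utilities=np.arange(1.0, N + 1.0),
    )
    return w, beliefs, brb
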