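"""Independent oracle: recursive two-source evidential-reasoning combination.

Fuses weighted belief distributions one rule at a time with the classic
recursive combination of basic probability masses (Dempster-Shafer style,
with the unassigned mass split into a weight-induced part and an
incompleteness-induced part).  The analytic closed form in the package must
agree with this sequential procedure; the oracle deliberately shares no code
with it.
"""

from __future__ import annotations

import numpy as np


def combine_er_recursive(weights: np.ndarray, beliefs: np.ndarray) -> np.ndarray:
    """Sequentially combine L discounted belief distributions.

    Parameters
    ----------
    weights:
        (L,) activation weights summing to 1.
    beliefs:
        (L, N) per-rule belief degrees (rows may sum to < 1).

    Returns
    -------
    (N,) aggregated belief distribution.
    """
    weights = np.asarray(weights, dtype=float)
    beliefs = np.asarray(beliefs, dtype=float)
    L, N = beliefs.shape

    # basic probability masses per rule
    def masses(k: int):
        m = weights[k] * beliefs[k]
        m_bar = 1.0 - weights[k]  # unassigned due to the rule's weight
        m_tilde = weights[k] * (1.0 - beliefs[k].sum())  # due to incompleteness
        return m, m_bar, m_tilde

    m, m_bar, m_tilde = masses(0)
    for k in range(1, L):
        m2, m2_bar, m2_tilde = masses(k)
        mD, m2D = m_bar + m_tilde, m2_bar + m2_tilde
        conflict = sum(
            m[i] * m2[j] for i in range(N) for j in range(N) if i != j
        )
        K = 1.0 / (1.0 - conflict)
        new_m = K * (m * m2 + m * m2D + mD * m2)
        new_m_tilde = K * (m_tilde * m2_tilde + m_tilde * m2_bar + m_bar * m2_tilde)
        new_m_bar = K * (m_bar * m2_bar)
        m, m_bar, m_tilde = new_m, new_m_bar, new_m_tilde

    return m / (1.0 - m_bar)
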