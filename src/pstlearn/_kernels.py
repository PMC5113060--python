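"""JIT-compiled likelihood kernels.

The per-trial Q-value recursion cannot be vectorised across trials, so the
sequential loops used inside maximum-likelihood fitting are compiled with
numba. The pure-Python replay in :mod:`pstlearn.qlearning` implements the
identical recursion and the two are cross-checked in the test suite.

Symbols are encoded as integers 0..5 (A..F). Probabilities are floored at
1e-300 before taking logs; the kernels return the number of floored trials so
callers can warn.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_FLOOR = 1e-300


@njit(cache=True)
def _p_choose(q_chosen: float, q_other: float, beta: float) -> float:
    x = (q_chosen - q_other) / beta
    # logistic, stable for large |x|
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def replay_kernel(
    chosen: np.ndarray,
    other: np.ndarray,
    outcome: np.ndarray,
    alpha_approach: float,
    alpha_avoid: float,
    beta: float,
    q0: float,
):
    """Replay observed training choices/outcomes.

    Returns (nll, final q over the six symbols, per-trial probability of the
    observed choice, number of probability-floored trials).
    """
    q = np.full(6, q0)
    n = chosen.shape[0]
    probs = np.empty(n)
    nll = 0.0
    floored = 0
    for t in range(n):
        c = chosen[t]
        p = _p_choose(q[c], q[other[t]], beta)
        if p < P_FLOOR:
            p = P_FLOOR
            floored += 1
        probs[t] = p
        nll -= np.log(p)
        pe = outcome[t] - q[c]
        if pe > 0.0:
            q[c] += alpha_approach * pe
        else:
            q[c] += alpha_avoid * pe
    return nll, q, probs, floored


@njit(cache=True)
def test_nll_kernel(
    q_final: np.ndarray,
    chosen: np.ndarray,
    other: np.ndarray,
    beta: float,
):
    """Score test-phase choices on frozen Q-values (no updating).

    Returns (nll, per-trial probabilities, floored count).
    """
    n = chosen.shape[0]
    probs = np.empty(n)
    nll = 0.0
    floored = 0
    for t in range(n):
        p = _p_choose(q_final[chosen[t]], q_final[other[t]], beta)
        if p < P_FLOOR:
            p = P_FLOOR
            floored += 1
        probs[t] = p
        nll -= np.log(p)
    return nll, probs, floored
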