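"""Independent oracles and builders shared across the test suite.

The likelihood oracles deliberately avoid the package's replay/kernel code
path: plain dicts, math.exp, and an explicit product of probabilities that
is only log-transformed at the end.
"""

from __future__ import annotations

import math

import numpy as np

from pstlearn.task import NOVEL_PAIRS, TRAINED_PAIRS, PairSpec, TrialRecord


def make_training_trial(pid, idx, pair_key, chosen, outcome, block=0):
    role = "trained" if pair_key in TRAINED_PAIRS else "novel"
    return TrialRecord(pid, "training", block, idx, PairSpec(pair_key[0], pair_key[1], role), chosen, outcome)


def make_test_trial(pid, idx, pair_key, chosen):
    return TrialRecord(pid, "test", None, idx, PairSpec(pair_key[0], pair_key[1], "novel"), chosen, None)


def brute_force_probs(trials, alpha_approach, alpha_avoid, beta, q0=0.5):
    """Probability of each observed training choice, by direct recursion on a
    dict of values."""
    q = {s: q0 for s in "ABCDEF"}
    probs = []
    for t in trials:
        other = t.pair.first if t.chosen == t.pair.second else t.pair.second
        p = 1.0 / (1.0 + math.exp(-(q[t.chosen] - q[other]) / beta))
        probs.append(p)
        pe = t.outcome - q[t.chosen]
        q[t.chosen] += (alpha_approach if pe > 0 else alpha_avoid) * pe
    return probs, q


def brute_force_nll_training(trials, alpha_approach, alpha_avoid, beta, q0=0.5):
    probs, _ = brute_force_probs(trials, alpha_approach, alpha_avoid, beta, q0)
    return -math.log(math.prod(probs))


def brute_force_nll_test(train, test, alpha_approach, alpha_avoid, beta, q0=0.5):
    _, q = brute_force_probs(train, alpha_approach, alpha_avoid, beta, q0)
    prod = 1.0
    for t in test:
        if t.chosen is None:
            continue
        other = t.pair.first if t.chosen == t.pair.second else t.pair.second
        prod *= 1.0 / (1.0 + math.exp(-(q[t.chosen] - q[other]) / beta))
    return -math.log(prod)


def random_training_log(rng, n_trials, pid="p"):
    trials = []
    for i in range(n_trials):
        key = TRAINED_PAIRS[rng.integers(3)]
        chosen = key[rng.integers(2)]
        trials.append(make_training_trial(pid, i, key, chosen, int(rng.integers(2))))
    return trials


def random_test_log(rng, n_trials, pid="p"):
    trials = []
    for i in range(n_trials):
        key = NOVEL_PAIRS[rng.integers(len(NOVEL_PAIRS))]
        chosen = key[rng.integers(2)]
        trials.append(make_test_trial(pid, i, key, chosen))
    return trials


def mixed_anova_interaction_F(y1, y2):
    """Brute-force split-plot (2 x 2-within) ANOVA interaction F from the
    classical sums-of-squares decomposition."""
    y = np.vstack([y1, y2])
    g = np.array([0] * len(y1) + [1] * len(y2))
    N, K = y.shape
    GM = y.mean()
    subj_mean = y.mean(axis=1)
    cell = np.array([[y[g == a][:, k].mean() for k in range(K)] for a in range(2)])
    gmean = np.array([y[g == a].mean() for a in range(2)])
    kmean = y.mean(axis=0)
    ss_int = sum(
        (g == a).sum() * (cell[a, k] - gmean[a] - kmean[k] + GM) ** 2
        for a in range(2)
        for k in range(K)
    )
    ss_err = sum(
        (y[i, k] - subj_mean[i] - cell[g[i], k] + gmean[g[i]]) ** 2
        for i in range(N)
        for k in range(K)
    )
    return (ss_int / (K - 1)) / (ss_err / ((N - 2) * (K - 1)))
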