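"""Independent brute-force oracles used to check the library's fast paths.

Everything here is deliberately naive — O(m*n) pair enumeration,
delete-one jackknife, label permutation — and shares no code with the
implementations under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_auc(scores, outcomes) -> float:
    """Mean over all case-control pairs of 1/0.5/0 (win/tie/loss)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    cases = s[y == 1]
    controls = s[y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))


def jackknife_auc_variance(scores, outcomes) -> float:
    """Delete-one jackknife variance of the empirical AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    n = len(s)
    theta = np.array(
        [brute_force_auc(np.delete(s, i), np.delete(y, i)) for i in range(n)]
    )
    return float((n - 1) / n * np.sum((theta - theta.mean()) ** 2))


def bootstrap_auc_variance(scores, outcomes, n_boot: int, rng) -> float:
    """Nonparametric bootstrap variance, resampling cases and controls
    separately (the two-sample scheme matching the AUC functional)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    cases = s[y == 1]
    controls = s[y == 0]
    stats = np.empty(n_boot)
    m, n = len(cases), len(controls)
    for b in range(n_boot):
        cb = np.sort(cases[rng.integers(0, m, m)])
        db = np.sort(controls[rng.integers(0, n, n)])
        below = np.searchsorted(db, cb, side="left")
        beq = np.searchsorted(db, cb, side="right")
        stats[b] = np.mean((below + 0.5 * (beq - below)) / n)
    return float(stats.var(ddof=1))


def permutation_auc_difference_p(
    scores_a, outcomes_a, scores_b, outcomes_b, n_perm: int, rng
) -> float:
    """Two-sided permutation p-value for |AUC_a - AUC_b|, permuting group
    membership of whole (score, outcome) records between the two groups."""
    obs = abs(brute_force_auc(scores_a, outcomes_a) - brute_force_auc(scores_b, outcomes_b))
    s = np.concatenate([scores_a, scores_b]).astype(float)
    y = np.concatenate([outcomes_a, outcomes_b])
    na = len(scores_a)
    count = 0
    trials = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(s))
        ya, yb = y[idx[:na]], y[idx[na:]]
        if ya.sum() == 0 or ya.sum() == na or yb.sum() == 0 or yb.sum() == len(yb):
            continue
        d = abs(brute_force_auc(s[idx[:na]], ya) - brute_force_auc(s[idx[na:]], yb))
        count += d >= obs - 1e-12
        trials += 1
    return (count + 1) / (trials + 1)


def exhaustive_cutpoint_scan(scores, outcomes, cutpoints, floor=None):
    """Directly scan 2x2 tables at every cut-point; return
    (best_youden_cut, best_constrained_cut_or_None) with lower-cut
    tie-breaks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    cases = s[y == 1]
    controls = s[y == 0]
    best_j, best_c = -np.inf, None
    best_jf, best_cf = -np.inf, None
    for c in cutpoints:
        sens = np.mean(cases >= c)
        spec = np.mean(controls < c)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
        if floor is not None and spec >= floor and j > best_jf + 1e-12:
            best_jf, best_cf = j, c
    return best_c, best_cf
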