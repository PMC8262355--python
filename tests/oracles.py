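"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: the
signed-rank and rank-sum nulls are enumerated literally, and neighbor
counting is an explicit all-pairs loop.
"""

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def signed_rank_p_bruteforce(deltas) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_min = min(w_obs, total - w_obs)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_min + 1e-12:
            count += 1
    return min(1.0, 2.0 * count / 2 ** n)


def rank_sum_p_bruteforce(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group-A subsets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size

    def u_stat(sample_a, sample_b):
        return sum((x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b)

    u_obs = u_stat(a, b)
    us = []
    idx = range(pooled.size)
    for comb in combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def neighbor_counts_loop(xy_a, xy_b, radius, same_set=False) -> np.ndarray:
    """Literal double loop neighbor count (inclusive boundary)."""
    counts = np.zeros(len(xy_a), dtype=int)
    for i, (xa, ya) in enumerate(xy_a):
        c = 0
        for xb, yb in xy_b:
            if np.hypot(xa - xb, ya - yb) <= radius:
                c += 1
        counts[i] = c - (1 if same_set else 0)
    return counts


def entropy_closed_form(p) -> float:
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    return float(-sum(pi * np.log(pi) for pi in p if pi > 0))
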