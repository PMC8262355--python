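"""Rank-test primitives shared by the genotyping and cohort modules.

The signed-rank test uses an exact null (all 2^n sign assignments) computed
by a rank-sum-distribution convolution that supports midrank ties, which the
stock exact routines do not; the large-sample path delegates to scipy.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .datatypes import ValidationError

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 20


def signed_rank_test(deltas) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired differences against 0.

    Zeros are dropped before ranking (Wilcoxon's treatment); ties get
    midranks. For n <= 25 nonzero differences the p-value is exact over the
    2^n equiprobable sign assignments (tie-aware); larger n uses the normal
    approximation with tie correction. All-zero input returns (0, 1).

    Returns ``(W_plus, p)`` where ``W_plus`` is the positive-rank sum.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValidationError("signed_rank_test: empty input")
    if not np.all(np.isfinite(d)):
        raise ValidationError("signed_rank_test: non-finite differences")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="approx", correction=False)
        p = float(res.pvalue)
    return w_plus, min(1.0, p)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    # Doubled ranks are integers even with midrank ties; convolve the
    # subset-sum distribution of W+ over all sign assignments.
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(np.rint(2 * w_plus))
    w_min2 = min(w2, total - w2)
    cdf_low = counts[: w_min2 + 1].sum() / counts.sum()
    return min(1.0, 2.0 * cdf_low)


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Exact p for combined n <= 20 without ties; otherwise the normal
    approximation with midrank tie correction and no continuity correction,
    so identical samples give p = 1 exactly.

    Returns ``(U, p)`` with U the Mann-Whitney statistic of the first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank_sum_test: both samples must be nonempty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("rank_sum_test: non-finite values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # fully degenerate: U at its null mean, zero variance
        return a.size * b.size / 2.0, 1.0
    method = "exact" if (not has_ties and pooled.size <= EXACT_RANK_SUM_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), min(1.0, float(res.pvalue))


def kruskal_wallis(groups, method: str = "asymptotic") -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction.

    ``method="asymptotic"`` (default) takes p from the chi-square reference;
    ``method="permutation"`` enumerates all assignments of the pooled values
    to the group sizes (only for total n <= 10) and reports
    P(H >= H_obs) under that exact null — useful for very small samples
    where the chi-square approximation is poor. The fully tie-degenerate
    case (every observation equal) returns (0, 1).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ValidationError("kruskal_wallis: need >= 2 nonempty groups")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    if method == "permutation":
        if pooled.size > 10:
            raise ValidationError("permutation method only for total n <= 10")
        p = _kw_permutation_p(arrs, float(h))
    elif method != "asymptotic":
        raise ValidationError(f"unknown method {method!r}")
    return float(h), float(p)


def _kw_permutation_p(arrs, h_obs: float) -> float:
    from itertools import permutations

    pooled = np.concatenate(arrs)
    sizes = [a.size for a in arrs]
    bounds = np.cumsum([0] + sizes)
    ge = total = 0
    for perm in permutations(range(pooled.size)):
        vals = pooled[list(perm)]
        groups = [vals[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
        if np.ptp(np.concatenate(groups)) == 0:
            h = 0.0
        else:
            h = float(sps.kruskal(*groups).statistic)
        total += 1
        if h >= h_obs - 1e-12:
            ge += 1
    return ge / total


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj
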