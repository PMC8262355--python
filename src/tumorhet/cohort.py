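"""Cohort-level inference.

Covers unsupervised patient grouping on genotype-frequency vectors
(agglomerative Ward/Euclidean), Kruskal-Wallis and rank-sum association
tests, and the contingency-table enrichment analysis used for mosaic plots:
Pearson residuals (O - E)/sqrt(E), whose squares sum to the overall chi2
statistic, with per-cell two-sided p-values from the standard-normal
reference — the conventional mosaic-plot approximation. No continuity
correction anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .datatypes import ValidationError
from .stats import kruskal_wallis, rank_sum_test  # noqa: F401  (rank_sum_test re-exported)


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame  # Pearson residuals; >0 = enriched, <0 = depleted
    chi2: float
    df: int
    p_overall: float
    p_per_cell: Optional[pd.DataFrame] = None


@dataclass
class GroupingResult:
    groups: pd.Series  # patient_id -> group in 1..n_groups
    linkage_record: np.ndarray
    per_genotype_kw: Optional[pd.DataFrame] = None


def cluster_patients(freq_vectors: pd.DataFrame, n_groups: int,
                     method: str = "ward") -> GroupingResult:
    """Agglomerative clustering of per-patient frequency vectors.

    ``freq_vectors`` is patients x categories (rows sum to 1). The
    dendrogram (default Ward linkage, Euclidean distance) is cut into
    ``n_groups`` flat groups, renumbered 1..n_groups in order of first
    appearance. Deterministic given the input.
    """
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")
    if len(freq_vectors) < n_groups:
        raise ValidationError(
            f"need >= {n_groups} patients, got {len(freq_vectors)}")
    x = freq_vectors.to_numpy(dtype=float)
    if len(freq_vectors) == 1:
        labels = np.array([1])
        lk = np.empty((0, 4))
    else:
        lk = linkage(x, method=method, metric="euclidean")
        labels = fcluster(lk, t=n_groups, criterion="maxclust")
    # renumber in order of first appearance for stable output
    remap: dict = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(lab, len(remap) + 1)
    return GroupingResult(pd.Series(out, index=freq_vectors.index, name="group"), lk)


def kruskal_by_group(freq_vectors: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-category Kruskal-Wallis test of frequencies across patient groups."""
    groups = groups.loc[freq_vectors.index]
    ids = sorted(groups.unique())
    if len(ids) < 2:
        raise ValidationError("need >= 2 groups")
    rows = []
    for cat in freq_vectors.columns:
        samples = [freq_vectors.loc[groups == g, cat].to_numpy() for g in ids]
        if any(len(s) == 0 for s in samples):
            raise ValidationError("empty group")
        h, p = kruskal_wallis(samples)
        rows.append({"category": cat, "H": h, "p_value": p})
    return pd.DataFrame(rows)


def _as_count_matrix(observed) -> pd.DataFrame:
    obs = observed if isinstance(observed, pd.DataFrame) else pd.DataFrame(np.asarray(observed))
    arr = obs.to_numpy(dtype=float)
    if arr.size == 0 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValidationError("observed counts must be nonnegative integers")
    if arr.sum() <= 0:
        raise ValidationError("empty contingency table")
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        raise ValidationError("all-zero row or column in contingency table")
    return obs.astype(float)


def chi2_independence(observed) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = _as_count_matrix(observed)
    chi2, p, df, expected = sps.chi2_contingency(obs.to_numpy(), correction=False)
    exp = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    resid = (obs - exp) / np.sqrt(exp)
    return ContingencyResult(obs, exp, resid, float(chi2), int(df), float(p))


def mosaic_residuals(observed) -> ContingencyResult:
    """Contingency enrichment analysis behind a mosaic plot.

    Adds per-cell two-sided p-values 2(1 - Phi(|r|)) from the Pearson
    residuals; the residual's sign reports direction (positive = observed
    above expectation). Accepts a count matrix or a cell-label table with
    ``cluster_id`` and ``treatment`` columns (cross-tabulated).
    """
    if isinstance(observed, pd.DataFrame) and {"cluster_id", "treatment"} <= set(observed.columns):
        observed = pd.crosstab(observed["cluster_id"], observed["treatment"])
    res = chi2_independence(observed)
    r = res.residuals
    p_cell = 2.0 * (1.0 - sps.norm.cdf(np.abs(r.to_numpy())))
    res.p_per_cell = pd.DataFrame(p_cell, index=r.index, columns=r.columns)
    return res


def contingency_long_format(res: ContingencyResult) -> pd.DataFrame:
    """Flatten a :class:`ContingencyResult` to long format for CSV output."""
    rows = []
    for i in res.observed.index:
        for j in res.observed.columns:
            rows.append({
                "row": i, "col": j,
                "observed": res.observed.at[i, j],
                "expected": res.expected.at[i, j],
                "residual": res.residuals.at[i, j],
                "p_cell": (res.p_per_cell.at[i, j]
                           if res.p_per_cell is not None else np.nan),
            })
    out = pd.DataFrame(rows)
    out.attrs.update(chi2=res.chi2, df=res.df, p_overall=res.p_overall)
    return out
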