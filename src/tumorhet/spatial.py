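"""Spatial statistics on cell centroids.

Three tools used throughout the pipeline:

* fixed-radius neighbor counting — for every cell of type A, the number of
  type-B cells whose nuclear centroid lies within a fixed radius (default
  75 um), averaged per case;
* Shannon entropy of category frequencies — the per-case heterogeneity
  index;
* k-means dispersion scoring — does a labeled subpopulation occupy a more
  compact spatial arrangement than a random subset of the same size? The
  statistic is the mean distance of the labeled cells to their assigned
  k-means centroid (k-means++ seeding, 10 restarts, best inertia), and the
  null is a label permutation: random draws of the same number of cells from
  the whole unit. Low values relative to the null mean mean clustering;
  ``score = w_obs / mean(w_null)`` and the one-sided add-one permutation
  p-value report it.

All distances are Euclidean on 2-D centroids; the radius boundary is
inclusive. The fixed-radius query uses a k-d tree whose results are
bit-identical to an all-pairs scan (the tree is an optimization, not a
semantic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .datatypes import ValidationError


@dataclass
class ProximityResult:
    case_id: str
    type_a: str
    type_b: str
    radius: float
    per_cell_counts: np.ndarray  # one count per type-A cell
    mean_count: float
    n_type_a: int


@dataclass
class DispersionScore:
    unit_id: str
    label: str
    n_label_cells: int
    k: int
    evaluable: bool
    w_obs: float = np.nan
    w_null_mean: float = np.nan
    score: float = np.nan
    p_clustered: float = np.nan
    n_permutations: int = 0


def neighbor_counts(cells: pd.DataFrame, type_a: str, type_b: str,
                    radius: float, type_column: str = "label",
                    case_id: str = "") -> ProximityResult:
    """Count type-B cells within ``radius`` of each type-A cell.

    ``cells`` needs columns x, y and ``type_column``. Distances are
    Euclidean between centroids, the boundary is inclusive, and a cell is
    never counted as its own neighbor when ``type_a == type_b``. A case
    with no type-A cells yields an empty, flagged result (mean 0 reported
    as NaN-free 0.0 with n_type_a = 0).
    """
    if radius <= 0:
        raise ValidationError(f"radius must be > 0, got {radius}")
    known = set(cells[type_column].unique())
    for t in (type_a, type_b):
        if t not in known:
            raise ValidationError(f"unknown type {t!r}; known types: {sorted(known)}")
    a = cells.loc[cells[type_column] == type_a, ["x", "y"]].to_numpy(dtype=float)
    b = cells.loc[cells[type_column] == type_b, ["x", "y"]].to_numpy(dtype=float)
    if len(a) == 0:
        return ProximityResult(case_id, type_a, type_b, radius,
                               np.zeros(0, dtype=int), 0.0, 0)
    tree = cKDTree(b)
    counts = np.asarray(tree.query_ball_point(a, r=radius, return_length=True),
                        dtype=int)
    if type_a == type_b:
        counts = counts - 1  # each cell finds itself at distance 0
    return ProximityResult(case_id, type_a, type_b, radius, counts,
                           float(counts.mean()), len(a))


def neighbor_counts_bruteforce(cells: pd.DataFrame, type_a: str, type_b: str,
                               radius: float, type_column: str = "label") -> np.ndarray:
    """All-pairs O(n^2) reference for :func:`neighbor_counts` (testing oracle)."""
    a = cells.loc[cells[type_column] == type_a, ["x", "y"]].to_numpy(dtype=float)
    b = cells.loc[cells[type_column] == type_b, ["x", "y"]].to_numpy(dtype=float)
    if len(a) == 0:
        return np.zeros(0, dtype=int)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    counts = (d2 <= radius ** 2).sum(axis=1)
    if type_a == type_b:
        counts = counts - 1
    return counts.astype(int)


def shannon_entropy(freq, base: str = "e") -> float:
    """Shannon entropy H = -sum p_i log p_i of category frequencies.

    ``freq`` is a mapping or sequence of nonnegative weights; it is
    renormalized to sum to 1, and 0 log 0 = 0. ``base`` is "e" (nats,
    default) or "2" (bits).
    """
    vals = np.asarray(list(freq.values()) if isinstance(freq, dict) else freq,
                      dtype=float)
    if vals.size == 0 or np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValidationError("frequencies must be finite and nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ValidationError("all-zero frequencies have no defined entropy")
    p = vals / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= np.log(2)
    elif base != "e":
        raise ValidationError(f"base must be 'e' or '2', got {base!r}")
    return h


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        tot = d2.sum()
        if tot <= 0:  # all points coincide with a chosen center
            centers[j:] = x[rng.integers(n, size=k - j)]
            return centers
        centers[j] = x[rng.choice(n, p=d2 / tot)]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers


def kmeans_fit(x: np.ndarray, k: int, rng: np.random.Generator,
               n_restarts: int = 10, max_iter: int = 300):
    """Plain Lloyd k-means with k-means++ seeding and restarts.

    Returns ``(inertia, centroid_distances)`` of the best restart, where
    ``centroid_distances`` is each point's Euclidean distance to its
    assigned centroid. Small point sets dominate the permutation-null use
    here, so a compact vectorized implementation is used.
    """
    best_inertia = np.inf
    best_dist = None
    for _ in range(n_restarts):
        centers = _kmeans_pp_init(x, k, rng)
        prev = None
        for _ in range(max_iter):
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)
            if prev is not None and np.array_equal(labels, prev):
                break
            prev = labels
            for j in range(k):
                mask = labels == j
                if mask.any():
                    centers[j] = x[mask].mean(axis=0)
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        dmin = np.sqrt(d2.min(axis=1))
        inertia = float((dmin ** 2).sum())
        if inertia < best_inertia:
            best_inertia = inertia
            best_dist = dmin
    return best_inertia, best_dist


def _dispersion_stat(coords: np.ndarray, k: int, rng: np.random.Generator) -> float:
    _, dist = kmeans_fit(coords, k, rng)
    return float(dist.mean())


def kmeans_dispersion(all_cells: pd.DataFrame, target_label: str,
                      config: Optional[AnalysisConfig] = None,
                      label_column: str = "label",
                      unit_id: str = "") -> DispersionScore:
    """Permutation-normalized spatial compactness of one labeled population.

    Observed statistic: mean distance of target-label cells to their
    assigned k-means centroid. Null: ``n_permutations`` draws of the same
    number of cells, uniformly without replacement from all cells in the
    unit, scored identically. ``p_clustered = (1 + #{null <= obs}) /
    (n_permutations + 1)`` is one-sided for clustering (small w_obs).
    Units with fewer target cells than ``min_cells_per_label`` or than k
    are flagged not-evaluable.
    """
    config = config or AnalysisConfig()
    seed = config.require_seed()
    labels = all_cells[label_column]
    if target_label not in set(labels.unique()):
        raise ValidationError(f"unknown label {target_label!r}")
    coords_all = all_cells[["x", "y"]].to_numpy(dtype=float)
    target = coords_all[(labels == target_label).to_numpy()]
    n = len(target)
    k = config.kmeans_k
    if n < max(config.min_cells_per_label, k):
        return DispersionScore(unit_id, target_label, n, k, evaluable=False)
    rng = np.random.default_rng(seed)
    w_obs = _dispersion_stat(target, k, rng)
    null = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        idx = rng.choice(len(coords_all), size=n, replace=False)
        null[i] = _dispersion_stat(coords_all[idx], k, rng)
    w_null_mean = float(null.mean())
    score = w_obs / w_null_mean if w_null_mean > 0 else np.nan
    p = (1.0 + np.count_nonzero(null <= w_obs)) / (config.n_permutations + 1.0)
    return DispersionScore(unit_id, target_label, n, k, True, w_obs,
                           w_null_mean, float(score), float(p),
                           config.n_permutations)
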