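"""Multiplexed-immunofluorescence phenotyping.

Single-cell mean intensities are thresholded per marker into binary calls;
an ordered gating tree combines the binary calls into lineages (first
matching lineage rule wins) and subtypes (evaluated only under their parent
lineage); tumor cells additionally receive a receptor category from the
HER2/ER binaries (HER2+ER- -> HER2, HER2-ER+ -> ER, HER2+ER+ -> HER2+ER+,
HER2-ER- -> DN). Case-level composition and Shannon-entropy heterogeneity
follow, plus unsupervised grouping of cases by their tumor receptor mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from scipy.stats import norm

from .datatypes import (IMMUNE_CATEGORIES, RECEPTOR_CATEGORIES, SchemaError,
                        ValidationError)
from .spatial import shannon_entropy

MIN_VALUES_AUTO_THRESHOLD = 50

#: subtype -> immune category entering the 4-way immune composition
IMMUNE_SUBTYPE_MAP = {
    "B cell": "B cell",
    "CD4 T": "CD4 T",
    "CD8 T": "CD8 T",
    "FoxP3+CD8+ T": "CD8 T",
    "macrophage": "macrophage",
    "GZM+ macrophage": "macrophage",
}

#: Shipped default 22-marker panel.
DEFAULT_PANEL = (
    "CK", "CD45", "CD3", "CD4", "CD8", "CD20", "CD68", "FoxP3", "GZMB",
    "HER2", "ER", "Vimentin", "CD31", "Ki67", "SMA", "PD1", "PDL1",
    "CD11b", "Ecad", "p53", "EGFR", "AR",
)

#: Shipped default gating tree covering the cell types named in the study;
#: fully overridable via a YAML gating config.
DEFAULT_GATING_TREE = [
    {"name": "tumor", "level": "lineage", "requires": {"CK": "+", "CD45": "-"},
     "output_label": "tumor"},
    {"name": "immune", "level": "lineage", "requires": {"CD45": "+"},
     "output_label": "immune"},
    {"name": "endothelial", "level": "lineage",
     "requires": {"CD31": "+", "CD45": "-", "CK": "-"},
     "output_label": "endothelial"},
    {"name": "stromal", "level": "lineage",
     "requires": {"Vimentin": "+", "CD45": "-", "CK": "-", "CD31": "-"},
     "output_label": "stromal"},
    {"name": "B cell", "level": "subtype", "parent": "immune",
     "requires": {"CD20": "+"}, "output_label": "B cell"},
    {"name": "FoxP3+CD8+ T", "level": "subtype", "parent": "immune",
     "requires": {"CD3": "+", "CD8": "+", "FoxP3": "+"},
     "output_label": "FoxP3+CD8+ T"},
    {"name": "CD8 T", "level": "subtype", "parent": "immune",
     "requires": {"CD3": "+", "CD8": "+"}, "output_label": "CD8 T"},
    {"name": "CD4 T", "level": "subtype", "parent": "immune",
     "requires": {"CD3": "+", "CD4": "+", "CD8": "-"}, "output_label": "CD4 T"},
    {"name": "GZM+ macrophage", "level": "subtype", "parent": "immune",
     "requires": {"CD68": "+", "GZMB": "+"}, "output_label": "GZM+ macrophage"},
    {"name": "macrophage", "level": "subtype", "parent": "immune",
     "requires": {"CD68": "+"}, "output_label": "macrophage"},
]


@dataclass
class GatingRule:
    name: str
    level: str  # "lineage" | "subtype"
    requires: Mapping[str, str]  # marker -> "+" / "-"
    output_label: str
    parent: Optional[str] = None


@dataclass
class GatingTree:
    """Ordered gating rules; document order is evaluation order."""

    rules: Sequence[GatingRule]

    def __post_init__(self) -> None:
        lineage_names = set()
        for r in self.rules:
            if r.level not in ("lineage", "subtype"):
                raise SchemaError(f"rule {r.name!r}: level must be lineage or subtype")
            if r.level == "lineage":
                if r.parent is not None:
                    raise SchemaError(f"lineage rule {r.name!r} cannot have a parent")
                lineage_names.add(r.name)
            else:
                if r.parent not in lineage_names:
                    raise SchemaError(
                        f"subtype rule {r.name!r}: parent {r.parent!r} is not a "
                        "preceding lineage rule")
            for marker, sign in r.requires.items():
                if sign not in ("+", "-"):
                    raise SchemaError(f"rule {r.name!r}: sign for {marker!r} must be + or -")

    def validate_panel(self, panel: Sequence[str]) -> None:
        missing = sorted({m for r in self.rules for m in r.requires} - set(panel))
        if missing:
            raise SchemaError(f"gating tree references markers absent from panel: {missing}")

    @classmethod
    def from_config(cls, rules) -> "GatingTree":
        return cls([GatingRule(name=r["name"], level=r["level"],
                               requires=dict(r["requires"]),
                               output_label=r.get("output_label", r["name"]),
                               parent=r.get("parent")) for r in rules])

    @classmethod
    def from_yaml(cls, path) -> "GatingTree":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise SchemaError(f"{path}: gating config must be a list of rules")
        return cls.from_config(raw)


def default_gating_tree() -> GatingTree:
    return GatingTree.from_config(DEFAULT_GATING_TREE)


@dataclass
class CaseComposition:
    case_id: str
    tumor_receptor_freq: dict = field(default_factory=dict)
    immune_freq: dict = field(default_factory=dict)
    n_tumor: int = 0
    n_immune: int = 0
    receptor_entropy: float = np.nan
    immune_entropy: float = np.nan


def estimate_threshold(values, method: str = "gmm2",
                       manual_value: Optional[float] = None,
                       random_state: int = 0) -> float:
    """Estimate a positivity threshold for one marker's intensities.

    gmm2
        Two-component Gaussian mixture on log(1 + intensity); the threshold
        is the posterior-0.5 crossing between the component means, mapped
        back to the intensity scale.
    otsu
        Maximizes between-class variance on a 256-bin histogram.
    manual
        Returns ``manual_value`` unchanged.

    Automatic methods require >= 50 values, reject constant input, and
    return a threshold strictly inside the observed range.
    """
    if method == "manual":
        if manual_value is None:
            raise ValidationError("manual thresholding requires a value")
        return float(manual_value)
    vals = np.asarray(values, dtype=float)
    if vals.size < MIN_VALUES_AUTO_THRESHOLD:
        raise ValidationError(
            f"automatic thresholding needs >= {MIN_VALUES_AUTO_THRESHOLD} values, "
            f"got {vals.size}")
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise ValidationError("intensities must be finite and nonnegative")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValidationError("constant input: no threshold exists")
    if method == "gmm2":
        thr = _gmm2_threshold(vals, random_state)
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(vals, nbins=256))
    else:
        raise ValidationError(f"unknown method {method!r}")
    eps = 1e-9 * (hi - lo)
    return float(np.clip(thr, lo + eps, hi - eps))


def _gmm2_threshold(vals: np.ndarray, random_state: int) -> float:
    from sklearn.mixture import GaussianMixture

    logv = np.log1p(vals).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    gm.fit(logv)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_
    lo_i, hi_i = np.argsort(means)

    def log_odds(x: float) -> float:
        # log P(high component) - log P(low component) at x
        hi_ll = np.log(w[hi_i]) + norm.logpdf(x, means[hi_i], sds[hi_i])
        lo_ll = np.log(w[lo_i]) + norm.logpdf(x, means[lo_i], sds[lo_i])
        return hi_ll - lo_ll

    a, b = means[lo_i], means[hi_i]
    if a == b:
        cross = a
    elif log_odds(a) * log_odds(b) < 0:
        cross = brentq(log_odds, a, b)
    else:  # no crossing between the means (extreme weights); use midpoint
        cross = 0.5 * (a + b)
    return float(np.expm1(cross))


def binarize(cells: pd.DataFrame, thresholds: Mapping[str, float]) -> pd.DataFrame:
    """Fill ``<marker>_bin`` columns: 1 iff intensity >= threshold (inclusive)."""
    missing = [m for m in thresholds if m not in cells.columns]
    if missing:
        raise SchemaError(f"markers absent from table: {missing}")
    out = cells.copy()
    for m, t in thresholds.items():
        out[m + "_bin"] = (out[m].to_numpy(dtype=float) >= t).astype(int)
    return out


def apply_gating(cells: pd.DataFrame, tree: GatingTree,
                 her2_marker: str = "HER2", er_marker: str = "ER") -> pd.DataFrame:
    """Assign lineage, subtype, and tumor receptor category per cell.

    Requires binary ``<marker>_bin`` columns. The first matching lineage
    rule in document order wins; subtype rules are evaluated only for cells
    of their parent lineage, again first match wins. Cells matching no rule
    at a level stay ``unassigned``. Order-independent across rows.
    """
    markers = {m for r in tree.rules for m in r.requires}
    missing = sorted(m for m in markers if m + "_bin" not in cells.columns)
    if missing:
        raise SchemaError(f"binary calls missing for markers: {missing}")
    out = cells.copy()
    n = len(out)
    lineage = np.full(n, "unassigned", dtype=object)
    subtype = np.full(n, "unassigned", dtype=object)
    lineage_of_rule = {r.name: r.output_label for r in tree.rules if r.level == "lineage"}

    def rule_mask(rule: GatingRule) -> np.ndarray:
        mask = np.ones(n, dtype=bool)
        for m, sign in rule.requires.items():
            col = out[m + "_bin"].to_numpy()
            mask &= (col == 1) if sign == "+" else (col == 0)
        return mask

    for rule in tree.rules:
        if rule.level != "lineage":
            continue
        mask = rule_mask(rule) & (lineage == "unassigned")
        lineage[mask] = rule.output_label
    for rule in tree.rules:
        if rule.level != "subtype":
            continue
        parent_label = lineage_of_rule[rule.parent]
        mask = rule_mask(rule) & (lineage == parent_label) & (subtype == "unassigned")
        subtype[mask] = rule.output_label
    out["lineage"] = lineage
    out["subtype"] = subtype

    receptor = np.full(n, "", dtype=object)
    tumor = lineage == "tumor"
    if tumor.any():
        her2 = out[her2_marker + "_bin"].to_numpy() == 1
        er = out[er_marker + "_bin"].to_numpy() == 1
        receptor[tumor & her2 & ~er] = "HER2"
        receptor[tumor & ~her2 & er] = "ER"
        receptor[tumor & her2 & er] = "HER2+ER+"
        receptor[tumor & ~her2 & ~er] = "DN"
    out["receptor"] = receptor
    return out


def case_composition(cells: pd.DataFrame, entropy_base: str = "e") -> list[CaseComposition]:
    """Tumor-receptor and immune compositions with Shannon entropies per case.

    Tumor receptor frequencies run over HER2 / ER / HER2+ER+ / DN; immune
    frequencies over B cell / CD4 T / CD8 T / macrophage (granzyme-positive
    macrophages and FoxP3+CD8+ T cells fold into their parent category).
    Cases lacking tumor (or classifiable immune) cells carry an empty map
    and an undefined (NaN) entropy for that axis.
    """
    results = []
    for case_id, grp in cells.groupby("case_id", sort=True):
        comp = CaseComposition(case_id=str(case_id))
        tum = grp[grp["lineage"] == "tumor"]
        comp.n_tumor = len(tum)
        if comp.n_tumor > 0:
            counts = tum["receptor"].value_counts()
            comp.tumor_receptor_freq = {c: counts.get(c, 0) / comp.n_tumor
                                        for c in RECEPTOR_CATEGORIES}
            comp.receptor_entropy = shannon_entropy(comp.tumor_receptor_freq,
                                                    base=entropy_base)
        imm = grp[grp["lineage"] == "immune"].copy()
        cat = imm["subtype"].map(IMMUNE_SUBTYPE_MAP)
        imm = imm[cat.notna()]
        comp.n_immune = len(imm)
        if comp.n_immune > 0:
            counts = cat.dropna().value_counts()
            comp.immune_freq = {c: counts.get(c, 0) / comp.n_immune
                                for c in IMMUNE_CATEGORIES}
            comp.immune_entropy = shannon_entropy(comp.immune_freq, base=entropy_base)
        results.append(comp)
    return results


def composition_table(compositions: Sequence[CaseComposition]) -> pd.DataFrame:
    rows = []
    for c in compositions:
        row = {"case_id": c.case_id, "n_tumor": c.n_tumor, "n_immune": c.n_immune,
               "receptor_entropy": c.receptor_entropy,
               "immune_entropy": c.immune_entropy}
        for cat in RECEPTOR_CATEGORIES:
            row[f"receptor:{cat}"] = c.tumor_receptor_freq.get(cat, np.nan)
        for cat in IMMUNE_CATEGORIES:
            row[f"immune:{cat}"] = c.immune_freq.get(cat, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def classify_case_subtype(compositions: Sequence[CaseComposition],
                          n_groups: int = 4,
                          dominance_cutoff: float = 0.5) -> pd.DataFrame:
    """Group cases by tumor receptor mix and name each group.

    Ward/Euclidean hierarchical clustering of the 4-vector receptor
    frequencies, cut into ``n_groups``; each group is labeled by its mean
    receptor mix's dominant category when that mean frequency reaches the
    dominance cutoff (default 0.5), else "mixed".
    """
    usable = [c for c in compositions if c.n_tumor > 0]
    if len(usable) < n_groups:
        raise ValidationError(
            f"need >= {n_groups} cases with tumor cells, got {len(usable)}")
    x = np.array([[c.tumor_receptor_freq[cat] for cat in RECEPTOR_CATEGORIES]
                  for c in usable])
    lk = linkage(x, method="ward", metric="euclidean")
    labels = fcluster(lk, t=n_groups, criterion="maxclust")
    rows = []
    group_names = {}
    for g in np.unique(labels):
        mean = x[labels == g].mean(axis=0)
        top = int(np.argmax(mean))
        group_names[g] = (RECEPTOR_CATEGORIES[top]
                          if mean[top] >= dominance_cutoff else "mixed")
    for c, g in zip(usable, labels):
        rows.append({"case_id": c.case_id, "group": int(g),
                     "subtype_group": group_names[g]})
    return pd.DataFrame(rows)
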