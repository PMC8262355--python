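"""In-situ genotype calling and genotype-frequency dynamics.

Each nucleus carries FISH spot counts for ERBB2 and the chromosome-17
centromere (CEP17) plus in-situ PCR counts for the mutant and wild-type
PIK3CA allele. A nucleus is called amplified when ERBB2:CEP17 >= 2 (clinical
FISH convention; configurable), or when no CEP17 signal was detected but the
absolute ERBB2 count reaches a fallback. The PIK3CA axis is mutant if any
mutant signal is present (a mutant allele dominates a co-detected wild-type
one), wild-type if only wild-type signal is present, undetermined otherwise.
Crossing the two axes yields the five genotype classes WT, Amp, Mut, WT-Amp
and Mut-Amp; nuclei uncallable on both axes are Undetermined and excluded
from every frequency.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datatypes import (GENOTYPES, UNDETERMINED, NucleusRecord,
                        ValidationError)
from .stats import signed_rank_test

SIGNED_RANK_TEST_LABEL = "wilcoxon-signed-rank, two-sided, vs 0"
MIN_PATIENTS_FOR_P = 3

_LEVEL_KEYS = {
    "image": ["patient_id", "sample_id", "timepoint", "image_id"],
    "sample": ["patient_id", "sample_id", "timepoint"],
    "patient": ["patient_id", "timepoint"],
}


def call_genotype(record: NucleusRecord, config: Optional[AnalysisConfig] = None) -> str:
    """Assign one of the five genotypes (or Undetermined) to a nucleus."""
    config = config or AnalysisConfig()
    if record.n_cep17 > 0:
        amplified = record.n_erbb2 / record.n_cep17 >= config.amp_ratio_threshold
    else:
        amplified = record.n_erbb2 >= config.amp_copy_fallback
    if record.n_mut >= config.min_total_pik3ca_signals:
        pik = "Mut"
    elif record.n_wt >= config.min_total_pik3ca_signals:
        pik = "WT"
    else:
        pik = None
    if pik is None:
        return "Amp" if amplified else UNDETERMINED
    if amplified:
        return f"{pik}-Amp"
    return pik


def call_genotypes(nuclei: pd.DataFrame, config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Vectorized genotype calling over a validated nucleus table.

    Returns a copy with the ``genotype`` column filled. Deterministic and
    independent of row order.
    """
    config = config or AnalysisConfig()
    erbb2 = nuclei["n_erbb2"].to_numpy(dtype=float)
    cep17 = nuclei["n_cep17"].to_numpy(dtype=float)
    mut = nuclei["n_mut"].to_numpy(dtype=float)
    wt = nuclei["n_wt"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_amp = (cep17 > 0) & (erbb2 / np.where(cep17 > 0, cep17, 1)
                                   >= config.amp_ratio_threshold)
    amplified = ratio_amp | ((cep17 == 0) & (erbb2 >= config.amp_copy_fallback))
    is_mut = mut >= config.min_total_pik3ca_signals
    is_wt = ~is_mut & (wt >= config.min_total_pik3ca_signals)
    geno = np.where(
        is_mut, np.where(amplified, "Mut-Amp", "Mut"),
        np.where(is_wt, np.where(amplified, "WT-Amp", "WT"),
                 np.where(amplified, "Amp", UNDETERMINED)))
    out = nuclei.copy()
    out["genotype"] = geno
    return out


def genotype_frequencies(nuclei: pd.DataFrame, level: str = "image") -> pd.DataFrame:
    """Genotype frequency tables at image, sample, or patient level.

    Image-level frequencies pool the image's determinate cells. Sample- and
    patient-level frequencies are the arithmetic mean of the constituent
    image-level frequency vectors rather than a cell pool, so images with
    unequal cell counts contribute equally; images with zero determinate
    cells are flagged (``evaluable = False``) and excluded from the mean.
    Output columns: the grouping keys, ``unit_id``, ``level``, ``n_cells``,
    ``evaluable`` and one frequency column per genotype.
    """
    if level not in _LEVEL_KEYS:
        raise ValidationError(f"level must be one of {sorted(_LEVEL_KEYS)}, got {level!r}")
    if "genotype" not in nuclei.columns or nuclei["genotype"].isna().any():
        raise ValidationError("genotype_frequencies: genotypes must be called first")

    img_keys = _LEVEL_KEYS["image"]
    rows = []
    for key, grp in nuclei.groupby(img_keys, sort=True):
        det = grp[grp["genotype"] != UNDETERMINED]
        n = len(det)
        row = dict(zip(img_keys, key))
        row["n_cells"] = n
        row["evaluable"] = n > 0
        counts = det["genotype"].value_counts()
        for g in GENOTYPES:
            row[g] = counts.get(g, 0) / n if n > 0 else 0.0
        rows.append(row)
    images = pd.DataFrame(rows)
    if level == "image":
        images["unit_id"] = images[img_keys].agg("/".join, axis=1)
        images["level"] = "image"
        return images

    keys = _LEVEL_KEYS[level]
    agg_rows = []
    for key, grp in images.groupby(keys, sort=True):
        ev = grp[grp["evaluable"]]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["n_cells"] = int(grp["n_cells"].sum())
        row["evaluable"] = len(ev) > 0
        for g in GENOTYPES:
            row[g] = float(ev[g].mean()) if len(ev) > 0 else 0.0
        agg_rows.append(row)
    out = pd.DataFrame(agg_rows)
    out["unit_id"] = out[keys].agg("/".join, axis=1)
    out["level"] = level
    return out


def frequency_change(pre: pd.DataFrame, post: pd.DataFrame):
    """Pre-to-post genotype-frequency change per patient, tested against 0.

    ``pre`` and ``post`` are patient-level frequency tables over the same
    patient set. For each genotype the per-patient delta is post - pre; the
    two-sided Wilcoxon signed-rank test (exact null for n <= 25, zeros
    dropped) asks whether deltas are centred at 0. With fewer than 3
    patients no p-value is reported (NaN).

    Returns ``(summary, deltas)``: a per-genotype summary frame
    (mean_delta, p_value, n_patients, test) and a patients x genotypes
    delta frame.
    """
    pre_p = pre[pre["evaluable"]].set_index("patient_id")
    post_p = post[post["evaluable"]].set_index("patient_id")
    missing_post = sorted(set(pre_p.index) - set(post_p.index))
    missing_pre = sorted(set(post_p.index) - set(pre_p.index))
    if missing_post or missing_pre:
        raise ValidationError(
            f"unmatched patients: missing post for {missing_post}, "
            f"missing pre for {missing_pre}")
    patients = sorted(pre_p.index)
    deltas = post_p.loc[patients, list(GENOTYPES)] - pre_p.loc[patients, list(GENOTYPES)]
    rows = []
    for g in GENOTYPES:
        d = deltas[g].to_numpy()
        if np.any(np.abs(d) > 1 + 1e-12):
            raise ValidationError(f"delta out of [-1, 1] for genotype {g}")
        if len(patients) >= MIN_PATIENTS_FOR_P:
            _, p = signed_rank_test(d)
        else:
            p = np.nan
        rows.append({"genotype": g, "mean_delta": float(d.mean()),
                     "p_value": p, "n_patients": len(patients),
                     "test": SIGNED_RANK_TEST_LABEL})
    return pd.DataFrame(rows), deltas


def topology_map(nuclei: pd.DataFrame, image_id: str, out: Optional[str] = None,
                 render: Optional[str] = None) -> pd.DataFrame:
    """Per-cell (x, y, genotype) table for one image; optional rendered map.

    ``render`` is a figure path (e.g. SVG); cells are colored by genotype in
    the fixed legend order WT, Amp, Mut, WT-Amp, Mut-Amp, Undetermined.
    """
    known = set(nuclei["image_id"])
    if image_id not in known:
        raise ValidationError(f"unknown image_id {image_id!r}; known: {sorted(known)[:10]}")
    sub = nuclei[nuclei["image_id"] == image_id]
    if "genotype" not in sub.columns or sub["genotype"].isna().any():
        raise ValidationError("topology_map: genotypes must be called first")
    table = sub[["nucleus_id", "x", "y", "genotype"]].reset_index(drop=True)
    if out is not None:
        from .io import write_table
        write_table(table, out)
    if render is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        palette = {"WT": "#4daf4a", "Amp": "#377eb8", "Mut": "#ff7f00",
                   "WT-Amp": "#984ea3", "Mut-Amp": "#e41a1c",
                   UNDETERMINED: "#999999"}
        fig, ax = plt.subplots(figsize=(6, 6))
        for g in list(GENOTYPES) + [UNDETERMINED]:
            pts = table[table["genotype"] == g]
            if len(pts):
                ax.scatter(pts["x"], pts["y"], s=12, c=palette[g], label=g)
        ax.invert_yaxis()
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.set_title(f"genotype topology — {image_id}")
        ax.legend(loc="upper right", fontsize=8)
        fig.savefig(render, bbox_inches="tight")
        plt.close(fig)
    return table
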