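"""Synthetic-data generators with attached ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — not the underlying microscopy or sequencing physics — and returns
the planted truth alongside the tables, so recovery can be checked without
any external download. Signal-count generation is defined relative to the
genotype-calling rule (guaranteeing recoverability for determinate cells)
rather than modeling FISH optics. All generators are bit-reproducible from
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GENOTYPES, UNDETERMINED, ValidationError

# ---------------------------------------------------------------------------
# STAR-FISH cohorts


@dataclass
class StarfishSimParams:
    """Study-condition defaults for the in-situ genotyping generator.

    Three images per sample matches the study's imaging design; the default
    pretreatment mixture is dominated by WT cells with a minor Mut-Amp
    clone, and ``treatment_delta`` shifts the posttreatment mixture
    (``delta_scale="frequency"``: additive on the frequency simplex with the
    unshifted genotypes rescaled proportionally; ``"logit"``: additive on
    log-frequencies, then renormalized).
    """

    n_patients: int = 10
    images_per_sample: int = 3
    cells_per_image: Tuple[float, float] = (300.0, 20.0)  # NB mean, dispersion
    genotype_mix_pre: Mapping[str, float] = field(default_factory=lambda: {
        "WT": 0.55, "Amp": 0.20, "WT-Amp": 0.10, "Mut": 0.05, "Mut-Amp": 0.10})
    treatment_delta: Mapping[str, float] = field(
        default_factory=lambda: {"Mut-Amp": 0.07})
    delta_scale: str = "frequency"
    undetermined_rate: float = 0.05
    spatial_mode: Mapping[str, str] = field(default_factory=dict)  # genotype -> uniform/clustered
    cluster_process: Tuple[int, float] = (3, 40.0)  # parents per image, offspring sd (um)
    field_um: Tuple[float, float] = (1000.0, 1000.0)
    seed: int = 0


def _check_simplex(mix: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    p = np.array([mix.get(g, 0.0) for g in names], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValidationError(f"mixture over {list(names)} must be a simplex, got {mix}")
    return p


def shifted_mixture(pre: Mapping[str, float], delta: Mapping[str, float],
                    scale: str = "frequency") -> dict:
    """Posttreatment genotype mixture implied by a treatment shift."""
    p = _check_simplex(pre, GENOTYPES)
    out = p.copy()
    if scale == "frequency":
        shifted = [g in delta for g in GENOTYPES]
        for i, g in enumerate(GENOTYPES):
            if g in delta:
                out[i] = p[i] + delta[g]
        rest_pre = p[~np.array(shifted)].sum()
        rest_target = 1.0 - out[np.array(shifted)].sum()
        if rest_pre > 0:
            out[~np.array(shifted)] *= rest_target / rest_pre
    elif scale == "logit":
        with np.errstate(divide="ignore"):
            logit = np.log(np.maximum(p, 1e-300))
        for i, g in enumerate(GENOTYPES):
            logit[i] += delta.get(g, 0.0)
        out = np.exp(logit - logit.max())
        out /= out.sum()
    else:
        raise ValidationError(f"delta_scale must be 'frequency' or 'logit', got {scale!r}")
    if np.any(out < -1e-12) or np.any(out > 1 + 1e-12):
        raise ValidationError("treatment shift leaves the simplex")
    out = np.clip(out, 0, None)
    out /= out.sum()
    return dict(zip(GENOTYPES, out))


def _signal_counts(genotype: str, rng: np.random.Generator) -> tuple[int, int, int, int]:
    """Draw (n_erbb2, n_cep17, n_mut, n_wt) that the default calling rule
    maps back to ``genotype``."""
    if genotype == UNDETERMINED:
        cep = int(rng.integers(1, 3))
        return cep, cep, 0, 0  # ratio 1, no PIK3CA signal
    amplified = genotype in ("Amp", "WT-Amp", "Mut-Amp")
    cep = int(rng.integers(1, 4))
    if amplified:
        erbb2 = 2 * cep + int(rng.poisson(2.0))  # ratio >= 2 guaranteed
    else:
        erbb2 = cep  # ratio 1 < 2
    if genotype in ("Mut", "Mut-Amp"):
        mut = 1 + int(rng.poisson(0.5))
        wt = int(rng.poisson(1.0))  # mutant signal dominates a co-detected WT
    elif genotype in ("WT", "WT-Amp"):
        mut = 0
        wt = 1 + int(rng.poisson(0.5))
    else:  # Amp: amplified, PIK3CA axis silent
        mut, wt = 0, 0
    return erbb2, cep, mut, wt


def _place_cells(genotypes: np.ndarray, params: StarfishSimParams,
                 rng: np.random.Generator) -> np.ndarray:
    w, h = params.field_um
    xy = np.column_stack([rng.uniform(0, w, len(genotypes)),
                          rng.uniform(0, h, len(genotypes))])
    n_parents, sd = params.cluster_process
    for g, mode in params.spatial_mode.items():
        if mode != "clustered":
            continue
        idx = np.flatnonzero(genotypes == g)
        if idx.size == 0:
            continue
        parents = np.column_stack([rng.uniform(0, w, n_parents),
                                   rng.uniform(0, h, n_parents)])
        assign = rng.integers(n_parents, size=idx.size)
        pts = parents[assign] + rng.normal(0, sd, size=(idx.size, 2))
        xy[idx] = np.clip(pts, [0, 0], [w, h])
    return xy


def simulate_starfish_cohort(params: Optional[StarfishSimParams] = None):
    """Generate a pre/post nucleus cohort with planted genotype mixtures.

    Returns ``(nuclei, truth)``: a nucleus table covering both timepoints
    (validating against the nucleus schema) and a truth dict with the
    planted mixtures and per-cell true genotypes (aligned Series;
    undetermined cells carry the Undetermined truth label).
    """
    params = params or StarfishSimParams()
    rng = np.random.default_rng(params.seed)
    pre_mix = _check_simplex(params.genotype_mix_pre, GENOTYPES)
    post_mix_map = shifted_mixture(params.genotype_mix_pre, params.treatment_delta,
                                   params.delta_scale)
    post_mix = np.array([post_mix_map[g] for g in GENOTYPES])
    if not 0 <= params.undetermined_rate < 1:
        raise ValidationError("undetermined_rate must be in [0, 1)")
    mean, disp = params.cells_per_image
    rows = []
    true_geno = []
    for pi in range(params.n_patients):
        patient = f"P{pi:03d}"
        for timepoint, mix in (("pre", pre_mix), ("post", post_mix)):
            sample = f"{patient}-{timepoint}"
            for ii in range(params.images_per_sample):
                image = f"{sample}-img{ii}"
                n = int(rng.negative_binomial(disp, disp / (disp + mean))) if disp > 0 \
                    else int(rng.poisson(mean))
                n = max(n, 1)
                genos = np.asarray(GENOTYPES)[rng.choice(len(GENOTYPES), size=n, p=mix)]
                undet = rng.random(n) < params.undetermined_rate
                genos = genos.astype(object)
                genos[undet] = UNDETERMINED
                xy = _place_cells(genos, params, rng)
                for ci in range(n):
                    erbb2, cep, mut, wt = _signal_counts(genos[ci], rng)
                    rows.append({
                        "patient_id": patient, "sample_id": sample,
                        "timepoint": timepoint, "image_id": image,
                        "nucleus_id": f"n{ci}", "x": xy[ci, 0], "y": xy[ci, 1],
                        "n_erbb2": erbb2, "n_cep17": cep,
                        "n_mut": mut, "n_wt": wt,
                    })
                    true_geno.append(genos[ci])
    nuclei = pd.DataFrame(rows)
    truth = {"mix_pre": dict(zip(GENOTYPES, pre_mix)),
             "mix_post": post_mix_map,
             "true_genotype": pd.Series(true_geno, index=nuclei.index)}
    return nuclei, truth


# ---------------------------------------------------------------------------
# CycIF cohorts

#: markers positive per simulated cell type (consistent with the default
#: gating tree); tumor cells add HER2/ER per their receptor category.
TYPE_POSITIVE_MARKERS = {
    "tumor": {"CK", "Ecad"},
    "B cell": {"CD45", "CD20"},
    "CD4 T": {"CD45", "CD3", "CD4"},
    "CD8 T": {"CD45", "CD3", "CD8"},
    "FoxP3+CD8+ T": {"CD45", "CD3", "CD8", "FoxP3"},
    "macrophage": {"CD45", "CD68", "CD11b"},
    "GZM+ macrophage": {"CD45", "CD68", "CD11b", "GZMB"},
    "stromal": {"Vimentin", "SMA"},
    "endothelial": {"CD31"},
}

RECEPTOR_POSITIVE = {"HER2": {"HER2"}, "ER": {"ER"},
                     "HER2+ER+": {"HER2", "ER"}, "DN": set()}


@dataclass
class CycifSimParams:
    """Defaults for the multiplexed-IF cohort generator.

    Marker intensities are log-normal: positive markers exp(N(mu1, sigma)),
    negative exp(N(mu0, sigma)) with a two-log-unit separation. Case tumor
    receptor mixes are Dirichlet-distributed around a cohort base mix, and
    pathologic complete response (pCR) follows a logistic model in the true
    HER2+ tumor fraction and CD8 T fraction — the generator's stated effect
    encoding "responders are HER2+-enriched".
    """

    n_cases: int = 20
    cells_per_case: int = 1000
    cell_type_mix: Mapping[str, float] = field(default_factory=lambda: {
        "tumor": 0.55, "CD4 T": 0.08, "CD8 T": 0.07, "B cell": 0.04,
        "macrophage": 0.05, "GZM+ macrophage": 0.02, "FoxP3+CD8+ T": 0.02,
        "stromal": 0.12, "endothelial": 0.05})
    tumor_receptor_base: Mapping[str, float] = field(default_factory=lambda: {
        "HER2": 0.40, "ER": 0.25, "HER2+ER+": 0.10, "DN": 0.25})
    tumor_receptor_concentration: float = 8.0
    mu0: float = 1.0
    mu1: float = 3.0
    sigma: float = 0.3
    pcr_intercept: float = -7.4
    pcr_slope_her2: float = 14.0
    pcr_slope_cd8: float = 4.0
    field_um: Tuple[float, float] = (1000.0, 1000.0)
    panel: Sequence[str] = None  # defaults to the shipped 22-marker panel
    seed: int = 0


def simulate_cycif_cohort(params: Optional[CycifSimParams] = None):
    """Generate per-cell marker-intensity tables with planted phenotypes.

    Returns ``(cells, case_truth, cell_truth)``: the cell table (case_id,
    cell coordinates, one intensity column per panel marker), a per-case
    truth frame (receptor mix, true HER2+ tumor fraction, CD8 fraction,
    pCR label), and a per-cell truth frame (true type, receptor category).
    """
    from .cycif import DEFAULT_PANEL

    params = params or CycifSimParams()
    panel = list(params.panel or DEFAULT_PANEL)
    rng = np.random.default_rng(params.seed)
    types = list(params.cell_type_mix)
    type_p = np.array([params.cell_type_mix[t] for t in types], dtype=float)
    if np.any(type_p < 0) or not np.isclose(type_p.sum(), 1.0, atol=1e-9):
        raise ValidationError("cell_type_mix must be a simplex")
    rec_cats = list(params.tumor_receptor_base)
    base = np.array([params.tumor_receptor_base[c] for c in rec_cats], dtype=float)
    if np.any(base <= 0) or not np.isclose(base.sum(), 1.0, atol=1e-9):
        raise ValidationError("tumor_receptor_base must be a positive simplex")
    unknown = set(types) - set(TYPE_POSITIVE_MARKERS)
    if unknown:
        raise ValidationError(f"no marker profile for cell types: {sorted(unknown)}")

    w, h = params.field_um
    cell_rows, cell_truth_rows, case_rows = [], [], []
    for ci in range(params.n_cases):
        case = f"case{ci:03d}"
        rec_mix = rng.dirichlet(params.tumor_receptor_concentration * base)
        n = params.cells_per_case
        t_idx = rng.choice(len(types), size=n, p=type_p)
        n_tumor = int((np.asarray(types)[t_idx] == "tumor").sum())
        receptors = np.asarray(rec_cats)[rng.choice(len(rec_cats), size=n, p=rec_mix)]
        xs = rng.uniform(0, w, n)
        ys = rng.uniform(0, h, n)
        her2_pos = 0
        cd8 = 0
        for j in range(n):
            ctype = types[t_idx[j]]
            positive = set(TYPE_POSITIVE_MARKERS[ctype])
            receptor = ""
            if ctype == "tumor":
                receptor = receptors[j]
                positive |= RECEPTOR_POSITIVE[receptor]
                if receptor in ("HER2", "HER2+ER+"):
                    her2_pos += 1
            if ctype in ("CD8 T", "FoxP3+CD8+ T"):
                cd8 += 1
            mu = np.where(np.isin(panel, list(positive)), params.mu1, params.mu0)
            intens = np.exp(rng.normal(mu, params.sigma))
            row = {"case_id": case, "block_id": "b0", "cell_id": f"{case}-c{j}",
                   "x": xs[j], "y": ys[j]}
            row.update(dict(zip(panel, intens)))
            cell_rows.append(row)
            cell_truth_rows.append({"case_id": case, "cell_id": row["cell_id"],
                                    "true_type": ctype, "true_receptor": receptor})
        her2_frac = her2_pos / n_tumor if n_tumor else 0.0
        cd8_frac = cd8 / n
        logit = (params.pcr_intercept + params.pcr_slope_her2 * her2_frac
                 + params.pcr_slope_cd8 * cd8_frac)
        pcr = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
        case_rows.append({"case_id": case, "pcr": pcr,
                          "her2_frac_true": her2_frac, "cd8_frac_true": cd8_frac,
                          **{f"receptor:{c}": rec_mix[k] for k, c in enumerate(rec_cats)}})
    cells = pd.DataFrame(cell_rows)
    return cells, pd.DataFrame(case_rows), pd.DataFrame(cell_truth_rows)


# ---------------------------------------------------------------------------
# Xenograft read scores


@dataclass
class ReadSimParams:
    """Two-population alignment-score generator (host vs graft reads).

    Human reads score ~40 points higher on the human genome than on mouse;
    mouse reads mirror this. Score noise is Gaussian per alignment.
    """

    n_reads: int = 10_000
    frac_human: float = 0.8
    human_scores: Tuple[float, float, float] = (100.0, 60.0, 5.0)  # mean_primary, mean_secondary, sd
    mouse_scores: Tuple[float, float, float] = (60.0, 100.0, 5.0)
    seed: int = 0


def simulate_read_scores(params: Optional[ReadSimParams] = None):
    """Generate dual-genome alignment scores with true species labels.

    Returns ``(reads, truth)`` where truth is a Series of "human"/"mouse"
    aligned with the read table.
    """
    params = params or ReadSimParams()
    if not 0 <= params.frac_human <= 1:
        raise ValidationError("frac_human must be in [0, 1]")
    for trio in (params.human_scores, params.mouse_scores):
        if trio[2] <= 0:
            raise ValidationError("score sd must be > 0")
    rng = np.random.default_rng(params.seed)
    n = params.n_reads
    is_human = rng.random(n) < params.frac_human
    hp, hs, hsd = params.human_scores
    mp, ms, msd = params.mouse_scores
    primary = np.where(is_human, rng.normal(hp, hsd, n), rng.normal(mp, msd, n))
    secondary = np.where(is_human, rng.normal(hs, hsd, n), rng.normal(ms, msd, n))
    reads = pd.DataFrame({"read_id": [f"r{i}" for i in range(n)],
                          "score_primary": primary, "score_secondary": secondary})
    truth = pd.Series(np.where(is_human, "human", "mouse"), index=reads.index,
                      name="species")
    return reads, truth


# ---------------------------------------------------------------------------
# Cluster x treatment label tables


def simulate_cluster_treatment_table(n_cells: int,
                                     cluster_probs: Mapping[str, float],
                                     treatment_probs: Mapping[str, float],
                                     planted_enrichment: Optional[Tuple[str, str, float]] = None,
                                     seed: int = 0,
                                     model_id: str = "model0"):
    """Generate a cell-by-(cluster, treatment) label table.

    The joint distribution is the product of the two marginals; an optional
    ``(cluster, treatment, multiplier)`` inflates (or deflates) one cell of
    the product table before renormalization, planting a known enrichment.
    Returns ``(labels, truth)`` where truth holds the joint probability
    table actually sampled from.
    """
    clusters = list(cluster_probs)
    treatments = list(treatment_probs)
    cp = _check_simplex(cluster_probs, clusters)
    tp = _check_simplex(treatment_probs, treatments)
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    joint = np.outer(cp, tp)
    if planted_enrichment is not None:
        cl, tr, mult = planted_enrichment
        if mult <= 0:
            raise ValidationError("multiplier must be > 0")
        joint[clusters.index(cl), treatments.index(tr)] *= mult
        joint /= joint.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, joint.ravel()).reshape(joint.shape)
    rows = []
    cid = 0
    for i, cl in enumerate(clusters):
        for j, tr in enumerate(treatments):
            for _ in range(counts[i, j]):
                rows.append({"cell_id": f"cell{cid}", "cluster_id": cl,
                             "treatment": tr, "model_id": model_id})
                cid += 1
    labels = pd.DataFrame(rows, columns=["cell_id", "cluster_id", "treatment", "model_id"])
    truth = {"joint": pd.DataFrame(joint, index=clusters, columns=treatments),
             "counts": pd.DataFrame(counts, index=clusters, columns=treatments)}
    return labels, truth
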