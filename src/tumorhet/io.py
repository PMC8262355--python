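"""Delimited-table readers/writers with row-level validation.

Tables are plain UTF-8 delimited text, comma or tab auto-detected from the
extension (``.csv``/``.tsv``); readers return validated
:class:`pandas.DataFrame` objects whose columns follow the canonical record
schemas in :mod:`tumorhet.datatypes`. A user-supplied ``schema`` mapping
(canonical name -> file column) adapts arbitrary column layouts.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SchemaError, ValidationError, TIMEPOINTS, GENOTYPES_ALL

NUCLEUS_COLUMNS = (
    "patient_id", "sample_id", "image_id", "nucleus_id",
    "x", "y", "n_erbb2", "n_cep17", "n_mut", "n_wt",
)
NUCLEUS_COUNT_COLUMNS = ("n_erbb2", "n_cep17", "n_mut", "n_wt")
SCORE_COLUMNS = ("read_id", "score_primary", "score_secondary")
LABEL_COLUMNS = ("cell_id", "cluster_id", "treatment", "model_id")


def detect_delimiter(path) -> str:
    """``\\t`` for .tsv/.tab, ``,`` otherwise."""
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab", ".txt") else ","


def _read_raw(path, schema: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=detect_delimiter(path), dtype=str,
                     keep_default_na=False, na_values=[])
    if df.shape[1] == 0 or (df.shape[0] == 0 and df.shape[1] == 0):
        raise ValidationError(f"{path}: empty input")
    if schema:
        missing_src = [v for v in schema.values() if v not in df.columns]
        if missing_src:
            raise SchemaError(f"{path}: schema maps to absent columns {missing_src}")
        df = df.rename(columns={v: k for k, v in schema.items()})
    if len(df) == 0:
        raise ValidationError(f"{path}: empty input (no data rows)")
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_float(df: pd.DataFrame, col: str, bad: dict) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    mask = ~np.isfinite(vals)
    for i in df.index[mask]:
        bad.setdefault(i, []).append(f"{col}={df.at[i, col]!r} not a finite number")
    return vals


def _coerce_count(df: pd.DataFrame, col: str, bad: dict) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    out = pd.Series(np.zeros(len(df), dtype=np.int64), index=df.index)
    for i in df.index:
        v = vals.at[i]
        if not np.isfinite(v) or v != np.floor(v) or v < 0:
            bad.setdefault(i, []).append(
                f"{col}={df.at[i, col]!r} is not a nonnegative integer")
        else:
            out.at[i] = int(v)
    return out


def _finalize(df, out, bad, path, errors):
    """Raise listing offending rows, or split valid/rejected (1-based rows)."""
    if bad:
        msgs = [f"row {i + 1}: {'; '.join(m)}" for i, m in sorted(bad.items())]
        if errors == "raise":
            raise ValidationError(f"{path}: {len(bad)} invalid row(s) — " + " | ".join(msgs))
        keep = out.drop(index=sorted(bad)).reset_index(drop=True)
        rejected = df.loc[sorted(bad)].copy()
        rejected["_row"] = [i + 1 for i in sorted(bad)]
        rejected["_reason"] = ["; ".join(bad[i]) for i in sorted(bad)]
        return keep, rejected.reset_index(drop=True)
    if errors == "raise":
        return out
    return out, df.iloc[0:0].copy()


def read_nucleus_table(path, schema: Optional[Mapping[str, str]] = None,
                       errors: str = "raise"):
    """Read a per-nucleus FISH signal-count table.

    Required columns (after ``schema`` renaming): patient_id, sample_id,
    image_id, nucleus_id, x, y and the four signal counts. ``timepoint``
    (pre/post/NA, default NA) and a pre-called ``genotype`` are optional.
    Counts given as integral floats ("2.0") are coerced; fractional counts
    are rejected. With ``errors="collect"`` returns ``(valid, rejected)``
    instead of raising.
    """
    df = _read_raw(path, schema)
    _require_columns(df, NUCLEUS_COLUMNS, path)
    bad: dict = {}
    out = pd.DataFrame(index=df.index)
    for c in ("patient_id", "sample_id", "image_id", "nucleus_id"):
        out[c] = df[c].astype(str)
    out["timepoint"] = df["timepoint"].astype(str) if "timepoint" in df.columns else "NA"
    for i in df.index:
        if out.at[i, "timepoint"] not in TIMEPOINTS:
            bad.setdefault(i, []).append(f"timepoint={out.at[i, 'timepoint']!r} invalid")
    out["x"] = _coerce_float(df, "x", bad)
    out["y"] = _coerce_float(df, "y", bad)
    for c in NUCLEUS_COUNT_COLUMNS:
        out[c] = _coerce_count(df, c, bad)
    if "genotype" in df.columns:
        out["genotype"] = df["genotype"].astype(str)
        for i in df.index:
            if out.at[i, "genotype"] not in GENOTYPES_ALL:
                bad.setdefault(i, []).append(f"genotype={out.at[i, 'genotype']!r} unknown")
    key = ["patient_id", "sample_id", "image_id", "nucleus_id"]
    dup = out.duplicated(subset=key, keep="first")
    for i in out.index[dup]:
        bad.setdefault(i, []).append("duplicate nucleus key " + str(tuple(out.loc[i, key])))
    return _finalize(df, out, bad, path, errors)


def read_cell_table(path, marker_panel: Sequence[str],
                    schema: Optional[Mapping[str, str]] = None,
                    errors: str = "raise"):
    """Read a per-cell marker-intensity table for a given marker panel.

    The header must contain x, y and every panel marker; case_id / block_id /
    cell_id are optional (defaulted when absent). Intensities must be finite
    and nonnegative. Cells start with lineage/subtype ``unassigned``.
    """
    df = _read_raw(path, schema)
    missing = [m for m in marker_panel if m not in df.columns]
    if missing:
        raise SchemaError(f"{path}: marker(s) absent from header: {missing}")
    _require_columns(df, ("x", "y"), path)
    bad: dict = {}
    out = pd.DataFrame(index=df.index)
    out["case_id"] = df["case_id"].astype(str) if "case_id" in df.columns else "case0"
    out["block_id"] = df["block_id"].astype(str) if "block_id" in df.columns else "block0"
    out["cell_id"] = (df["cell_id"].astype(str) if "cell_id" in df.columns
                      else [f"c{i}" for i in df.index])
    out["x"] = _coerce_float(df, "x", bad)
    out["y"] = _coerce_float(df, "y", bad)
    for m in marker_panel:
        vals = _coerce_float(df, m, bad)
        neg = vals < 0
        for i in df.index[neg & np.isfinite(vals)]:
            bad.setdefault(i, []).append(f"{m}={vals.at[i]} negative intensity")
        out[m] = vals
    out["lineage"] = "unassigned"
    out["subtype"] = "unassigned"
    return _finalize(df, out, bad, path, errors)


def read_score_table(path, schema: Optional[Mapping[str, str]] = None,
                     errors: str = "raise"):
    """Read a read_id / score_primary / score_secondary alignment-score table."""
    df = _read_raw(path, schema)
    _require_columns(df, SCORE_COLUMNS, path)
    bad: dict = {}
    out = pd.DataFrame(index=df.index)
    out["read_id"] = df["read_id"].astype(str)
    out["score_primary"] = _coerce_float(df, "score_primary", bad)
    out["score_secondary"] = _coerce_float(df, "score_secondary", bad)
    dup = out.duplicated(subset=["read_id"], keep="first")
    for i in out.index[dup]:
        bad.setdefault(i, []).append(f"duplicate read_id {out.at[i, 'read_id']!r}")
    return _finalize(df, out, bad, path, errors)


def read_label_table(path, schema: Optional[Mapping[str, str]] = None,
                     errors: str = "raise"):
    """Read a cell_id / cluster_id / treatment / model_id label table."""
    df = _read_raw(path, schema)
    _require_columns(df, LABEL_COLUMNS, path)
    bad: dict = {}
    out = pd.DataFrame(index=df.index)
    for c in LABEL_COLUMNS:
        out[c] = df[c].astype(str)
        for i in df.index:
            if out.at[i, c] == "":
                bad.setdefault(i, []).append(f"{c} empty")
    dup = out.duplicated(subset=["cell_id", "model_id"], keep="first")
    for i in out.index[dup]:
        bad.setdefault(i, []).append("duplicate (cell_id, model_id)")
    return _finalize(df, out, bad, path, errors)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as delimited text (delimiter from extension).

    Floats are written with full round-trip precision so write-then-read
    reproduces every numeric field bit-identically.
    """
    df.to_csv(path, sep=detect_delimiter(path), index=False, float_format=None)
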