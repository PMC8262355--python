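"""Shared domain types and errors.

The pipeline's tabular containers are plain :class:`pandas.DataFrame` objects
validated on read (see :mod:`tumorhet.io`); the dataclasses here define the
per-record schema and are used for single-record operations such as
:func:`tumorhet.starfish.call_genotype`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The five determinate genotype classes, in fixed display order:
#: ERBB2 amplification status crossed with PIK3CA H1047R mutation status.
GENOTYPES = ("WT", "Amp", "Mut", "WT-Amp", "Mut-Amp")

#: Sentinel for nuclei where neither axis could be called.
UNDETERMINED = "Undetermined"

GENOTYPES_ALL = GENOTYPES + (UNDETERMINED,)

TIMEPOINTS = ("pre", "post", "NA")

LINEAGES = ("tumor", "immune", "stromal", "endothelial", "other", "unassigned")

#: Tumor receptor categories derived from HER2/ER binary calls.
RECEPTOR_CATEGORIES = ("HER2", "ER", "HER2+ER+", "DN")

#: Immune subtypes entering the immune diversity index.
IMMUNE_CATEGORIES = ("B cell", "CD4 T", "CD8 T", "macrophage")


class TumorhetError(Exception):
    """Base class for all package errors."""


class SchemaError(TumorhetError):
    """A required column or configuration key is missing or malformed."""


class ValidationError(TumorhetError):
    """Row-level content violates a record invariant."""


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus with per-channel FISH/PCR signal counts.

    ``n_erbb2`` / ``n_cep17`` are FISH spot counts for the ERBB2 probe and the
    chromosome-17 centromere reference; ``n_mut`` / ``n_wt`` are in-situ PCR
    signal counts for the mutant and wild-type PIK3CA allele. Coordinates are
    nuclear-centroid positions in micrometers (image convention: origin
    top-left, y down).
    """

    patient_id: str
    sample_id: str
    timepoint: str
    image_id: str
    nucleus_id: str
    x: float
    y: float
    n_erbb2: int
    n_cep17: int
    n_mut: int
    n_wt: int
    genotype: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("n_erbb2", "n_cep17", "n_mut", "n_wt"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"coordinates must be finite, got ({self.x}, {self.y})")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if self.genotype is not None and self.genotype not in GENOTYPES_ALL:
            raise ValidationError(f"unknown genotype {self.genotype!r}")


@dataclass
class CycifCellRecord:
    """One cell from a cyclic-immunofluorescence run.

    ``intensity`` maps marker name to single-cell mean intensity; ``binary``
    holds the thresholded calls (filled by :func:`tumorhet.cycif.binarize`).
    ``lineage``/``subtype`` are assigned by the gating tree.
    """

    case_id: str
    block_id: str
    cell_id: str
    x: float
    y: float
    intensity: dict = field(default_factory=dict)
    binary: dict = field(default_factory=dict)
    lineage: str = "unassigned"
    subtype: str = "unassigned"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"coordinates must be finite, got ({self.x}, {self.y})")
        for m, v in self.intensity.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"intensity[{m}] must be finite and >= 0, got {v!r}")
        if not set(self.binary) <= set(self.intensity):
            raise ValidationError("binary keys must be a subset of intensity keys")
        if self.lineage not in LINEAGES:
            raise ValidationError(f"lineage must be one of {LINEAGES}, got {self.lineage!r}")


@dataclass(frozen=True)
class ClusterLabelRecord:
    """One cell's cluster assignment, treatment arm, and source model."""

    cell_id: str
    cluster_id: str
    treatment: str
    model_id: str

    def __post_init__(self) -> None:
        for name in ("cell_id", "cluster_id", "treatment", "model_id"):
            v = getattr(self, name)
            if v is None or str(v) == "":
                raise ValidationError(f"{name} must be non-empty")


@dataclass(frozen=True)
class ReadScoreRecord:
    """One sequencing read's best alignment scores to the primary (human)
    and secondary (mouse) genomes."""

    read_id: str
    score_primary: float
    score_secondary: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.score_primary) and np.isfinite(self.score_secondary)):
            raise ValidationError(
                f"read {self.read_id!r}: scores must be finite, got "
                f"({self.score_primary}, {self.score_secondary})"
            )
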