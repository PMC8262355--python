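"""Analysis configuration: defaults, validation, YAML loading.

Only two constants are fixed by the study design — the 75 um proximity
radius and the P <= 0.01 significance level of the read-deconvolution t
test; everything else is an overridable default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml

from .datatypes import SchemaError


@dataclass
class DeconvParams:
    """Parameters of the resampling threshold procedure for xenograft reads.

    grid
        Candidate minimum human-minus-mouse alignment-score differences,
        ascending.
    sample_size / n_reps
        Each candidate is assessed by ``n_reps`` random draws of
        ``sample_size`` eligible reads.
    alpha
        Per-draw paired-t significance level (study value 0.01).
    confidence_frac
        Fraction of draws that must be significant for a candidate to count
        as "confidently" species-biased.
    """

    grid: Sequence[float] = field(default_factory=lambda: list(range(0, 55, 5)))
    sample_size: int = 100
    n_reps: int = 50
    alpha: float = 0.01
    confidence_frac: float = 0.95

    def validate(self) -> None:
        if len(self.grid) == 0:
            raise SchemaError("deconv.grid must be nonempty")
        if list(self.grid) != sorted(self.grid):
            raise SchemaError("deconv.grid must be ascending")
        if self.sample_size < 2:
            raise SchemaError("deconv.sample_size must be >= 2")
        if self.n_reps < 1:
            raise SchemaError("deconv.n_reps must be >= 1")
        if not (0 < self.alpha < 1):
            raise SchemaError("deconv.alpha must be in (0, 1)")
        if not (0 < self.confidence_frac <= 1):
            raise SchemaError("deconv.confidence_frac must be in (0, 1]")


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with their defaults.

    amp_ratio_threshold
        Minimum ERBB2:CEP17 signal ratio calling a nucleus amplified
        (clinical FISH convention, 2.0).
    amp_copy_fallback
        Absolute ERBB2 count calling amplification when no CEP17 reference
        signal was detected.
    min_total_pik3ca_signals
        Minimum PCR signal count needed to call the PIK3CA axis.
    radius_um
        Fixed neighborhood radius for proximity counting (study value 75 um).
    entropy_log_base
        "e" (nats) or "2" (bits) for Shannon entropy.
    kmeans_k, min_cells_per_label, n_permutations
        Spatial-dispersion scoring parameters.
    n_patient_groups
        Number of groups cut from the patient dendrogram.
    random_seed
        Mandatory for any stochastic operation.
    """

    amp_ratio_threshold: float = 2.0
    amp_copy_fallback: int = 6
    min_total_pik3ca_signals: int = 1
    radius_um: float = 75.0
    entropy_log_base: str = "e"
    kmeans_k: int = 3
    min_cells_per_label: int = 20
    n_permutations: int = 999
    n_patient_groups: int = 4
    random_seed: Optional[int] = None
    deconv: DeconvParams = field(default_factory=DeconvParams)

    def validate(self) -> None:
        positive = (
            "amp_ratio_threshold",
            "amp_copy_fallback",
            "min_total_pik3ca_signals",
            "radius_um",
            "kmeans_k",
            "min_cells_per_label",
            "n_permutations",
            "n_patient_groups",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise SchemaError(f"{name} must be > 0")
        if self.entropy_log_base not in ("e", "2"):
            raise SchemaError("entropy_log_base must be 'e' or '2'")
        self.deconv.validate()

    def require_seed(self) -> int:
        if self.random_seed is None:
            raise SchemaError("random_seed must be set for stochastic operations")
        return int(self.random_seed)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key/value file.

    Unknown keys are rejected so typos fail at load time; nested ``deconv``
    keys override :class:`DeconvParams` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    deconv_raw = raw.pop("deconv", {})
    known = set(AnalysisConfig.__dataclass_fields__) - {"deconv"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    dk = set(DeconvParams.__dataclass_fields__)
    unknown_d = set(deconv_raw) - dk
    if unknown_d:
        raise SchemaError(f"unknown deconv config keys: {sorted(unknown_d)}")
    cfg = AnalysisConfig(**raw, deconv=DeconvParams(**deconv_raw))
    cfg.validate()
    return cfg
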