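"""Human/mouse read disambiguation for xenograft sequencing.

Reads from a patient-derived xenograft align to both the human (primary)
and mouse (secondary) genomes; reads mapping uniquely to both need a rule.
The rule is a minimum human-minus-mouse alignment-score difference d*,
chosen by resampling: for each candidate d on a grid, draw repeated random
samples of the reads whose difference is at least d and compare their human
vs mouse scores with a paired two-sided t test; d* is the smallest candidate
at which nearly all (default 95%) of the draws are significant at
P <= 0.01. Reads with difference >= d* (inclusive) are kept as human.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DeconvParams
from .datatypes import ValidationError

#: Sentinel threshold when no grid candidate reaches the confidence bar.
NO_THRESHOLD = "none"


@dataclass
class ThresholdResult:
    threshold: Union[float, str]  # d* or the sentinel "none"
    grid: list
    per_candidate: Mapping[float, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {"threshold": self.threshold, "grid": list(self.grid),
                "per_candidate": {str(k): v for k, v in self.per_candidate.items()},
                "params": dict(self.params)}


def score_differences(reads: pd.DataFrame) -> pd.Series:
    """Per-read human-minus-mouse alignment-score difference (order-preserving)."""
    return reads["score_primary"] - reads["score_secondary"]


def _paired_t_p(primary: np.ndarray, secondary: np.ndarray) -> float:
    d = primary - secondary
    if np.ptp(d) == 0 and d.std() == 0:
        # zero-variance differences carry no evidence of species bias
        return 1.0
    res = sps.ttest_rel(primary, secondary, alternative="two-sided")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def determine_threshold(reads: pd.DataFrame, params: Optional[DeconvParams] = None,
                        seed: Optional[int] = None) -> ThresholdResult:
    """Resampling choice of the minimum retained score difference d*.

    For each candidate d in the ascending grid: the eligible set is the
    reads with difference >= d; ``n_reps`` samples of ``sample_size`` reads
    are drawn without replacement and each tested with a paired two-sided t
    test of primary vs secondary score. A candidate with fewer eligible
    reads than the sample size is recorded not-evaluable. d* is the minimum
    candidate whose fraction of significant draws (p <= alpha) reaches
    ``confidence_frac``; the sentinel "none" when no candidate qualifies.
    """
    params = params or DeconvParams()
    params.validate()
    if seed is None:
        raise ValidationError("determine_threshold requires a seed")
    if len(reads) == 0:
        raise ValidationError("empty read set")
    rng = np.random.default_rng(seed)
    diffs = score_differences(reads).to_numpy()
    primary = reads["score_primary"].to_numpy(dtype=float)
    secondary = reads["score_secondary"].to_numpy(dtype=float)
    per_candidate: dict = {}
    threshold: Union[float, str] = NO_THRESHOLD
    for d in params.grid:
        eligible = np.flatnonzero(diffs >= d)
        entry: dict = {"n_eligible_reads": int(eligible.size)}
        if eligible.size < params.sample_size:
            entry["frac_reps_significant"] = None
            entry["evaluable"] = False
        else:
            sig = 0
            for _ in range(params.n_reps):
                idx = rng.choice(eligible, size=params.sample_size, replace=False)
                if _paired_t_p(primary[idx], secondary[idx]) <= params.alpha:
                    sig += 1
            frac = sig / params.n_reps
            entry["frac_reps_significant"] = frac
            entry["evaluable"] = True
            if threshold == NO_THRESHOLD and frac >= params.confidence_frac:
                threshold = float(d)
        per_candidate[float(d)] = entry
    return ThresholdResult(threshold, list(params.grid), per_candidate,
                           {"m": params.sample_size, "R": params.n_reps,
                            "alpha": params.alpha,
                            "confidence_frac": params.confidence_frac,
                            "seed": seed})


def filter_reads(reads: pd.DataFrame, threshold: Union[float, str]) -> set:
    """Read ids retained as confidently human: difference >= threshold.

    The boundary is inclusive. A "none" threshold retains nothing from the
    ambiguous set (conservative).
    """
    if threshold == NO_THRESHOLD:
        return set()
    diffs = score_differences(reads)
    keep = reads.loc[diffs >= float(threshold), "read_id"]
    return set(keep.astype(str))
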