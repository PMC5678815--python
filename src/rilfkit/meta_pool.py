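"""Fixed-effect pooling of alpha/beta estimates across studies.

Study-level alpha/beta ratios (Gy) with standard errors are combined
by inverse-variance weighting: w_i = 1/SE_i^2, pooled mean
sum(w x)/sum(w), pooled SE 1/sqrt(sum(w)).  Because published pooled
figures do not always state their weighting, the unweighted mean +- SD
is always co-reported.  Forest-plot rows carry 95% Wald intervals
(+-1.96 SE) and normalised percentage weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["MetaStudyRecord", "PooledResult", "pool_fixed", "forest_table"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MetaStudyRecord:
    label: str
    alpha_beta: float
    se: float
    endpoint: str = ""
    strain: str = ""
    followup: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"study {self.label!r}: SE must be > 0")


@dataclass(frozen=True)
class PooledResult:
    mean: float
    se: float
    unweighted_mean: float
    unweighted_sd: float
    n_studies: int


def pool_fixed(studies) -> PooledResult:
    """Inverse-variance fixed-effect pooled alpha/beta (Gy)."""
    studies = list(studies)
    if not studies:
        raise ValidationError("no studies to pool")
    x = np.array([s.alpha_beta for s in studies], dtype=float)
    se = np.array([s.se for s in studies], dtype=float)
    if np.any(se <= 0):
        raise ValidationError("all study SEs must be > 0")
    w = 1.0 / se ** 2
    return PooledResult(
        mean=float(np.sum(w * x) / np.sum(w)),
        se=float(1.0 / np.sqrt(np.sum(w))),
        unweighted_mean=float(x.mean()),
        unweighted_sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        n_studies=len(studies),
    )


def forest_table(studies, pooled: PooledResult) -> pd.DataFrame:
    """Forest-plot rows: per-study estimate, 95% CI and weight (%),
    plus a final pooled row (weight 100)."""
    studies = list(studies)
    if pooled.n_studies != len(studies):
        raise ValidationError("pooled result does not match the study list")
    se = np.array([s.se for s in studies], dtype=float)
    w = 1.0 / se ** 2
    w_pct = 100.0 * w / w.sum()
    rows = [
        {"label": s.label, "estimate": s.alpha_beta,
         "lower95": s.alpha_beta - _Z95 * s.se,
         "upper95": s.alpha_beta + _Z95 * s.se,
         "weight_pct": float(wp)}
        for s, wp in zip(studies, w_pct)
    ]
    rows.append({"label": "pooled (fixed)", "estimate": pooled.mean,
                 "lower95": pooled.mean - _Z95 * pooled.se,
                 "upper95": pooled.mean + _Z95 * pooled.se,
                 "weight_pct": 100.0})
    return pd.DataFrame(rows)
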