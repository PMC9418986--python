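"""Descriptive linear trends: diversity against year and against ASMR.

Ordinary least squares by the closed-form normal equations; slopes and R^2
are reported descriptively, without standard errors, matching how the trend
lines are drawn in the figures this analysis produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class TrendFit:
    label: tuple
    predictor: str  # "year" or "asmr"
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_trend(
    xs: Sequence[float],
    ys: Sequence[float],
    label: tuple = (),
    predictor: str = "year",
) -> TrendFit:
    """OLS line through (xs, ys) with R^2 = 1 - SSE/SST.

    Needs at least 3 points and non-constant xs.  Constant ys give slope 0
    and R^2 = 0 (SST = 0 is read as "no variance explained").
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend fit")
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0:
        raise ValueError("predictor is constant; slope undefined")
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    sst = np.sum((y - ybar) ** 2)
    sse = np.sum((y - (intercept + slope * x)) ** 2)
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    return TrendFit(
        label=tuple(label),
        predictor=predictor,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=int(x.size),
    )
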