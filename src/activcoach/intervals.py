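"""Naive probabilistic prediction intervals around point step forecasts.

A point forecast Ŷ_{T+h} becomes an interval Ŷ_{T+h} ± c·σ_h where σ_h is the
residual standard deviation of the one-step naive ("tomorrow equals today")
forecast and c is the normal coverage constant (1.28 for an 80% interval).
σ_h is held constant across the 7-day horizon by default; optional √h
widening is available for users who prefer the textbook random-walk growth.

Bounds are reported in whole steps.  The default convention truncates both
raw bounds to whole steps (``rounding="floor"``); ``"half-up"`` and
``"inward"`` (ceil the lower bound, floor the upper) are also supported, as
published tables differ on this point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rounding import half_up_int, round_half_up
from .errors import ArityError, DomainError, InsufficientDataError

#: normal coverage constants by interval probability
COVERAGE_C = {0.80: 1.28, 0.90: 1.645, 0.95: 1.96}

_ROUNDINGS = ("floor", "half-up", "inward")


@dataclass(frozen=True)
class PredictionInterval:
    h: int            # horizon step index, >= 1
    point: float      # point forecast, steps
    c: float          # coverage constant
    sigma_h: float    # residual SD, steps
    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.h < 1:
            raise DomainError("horizon index h must be >= 1")
        if not self.lower <= self.upper:
            raise DomainError("lower bound exceeds upper bound")


def naive_residual_sd(series: Sequence[float]) -> float:
    """Sample SD of the one-step naive forecast residuals e_t = y_t - y_{t-1}."""
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise InsufficientDataError(
            "need at least 3 observations for naive residuals")
    return float(np.std(np.diff(y), ddof=1))


def _round_bounds(lower_raw: float, upper_raw: float,
                  rounding: str) -> tuple[int, int]:
    if rounding == "floor":
        return math.floor(lower_raw), math.floor(upper_raw)
    if rounding == "half-up":
        return half_up_int(lower_raw), half_up_int(upper_raw)
    if rounding == "inward":
        return math.ceil(lower_raw), math.floor(upper_raw)
    raise DomainError(f"rounding must be one of {_ROUNDINGS}, got {rounding!r}")


def prediction_interval(point: float, c: float, sigma_h: float, h: int = 1,
                        rounding: str = "floor",
                        floor_at_zero: bool = False,
                        widen_with_horizon: bool = False) -> PredictionInterval:
    """Build the interval ``point ± c·sigma_h`` with integer step bounds.

    The raw bounds are exactly symmetric about the point; the configured
    ``rounding`` then maps them to whole steps.  With ``floor_at_zero`` the
    lower bound is clamped at 0 (step counts cannot be negative); off by
    default so the arithmetic stays transparent.
    """
    if sigma_h < 0:
        raise DomainError("sigma_h must be non-negative")
    margin = c * sigma_h * (math.sqrt(h) if widen_with_horizon else 1.0)
    lower, upper = _round_bounds(point - margin, point + margin, rounding)
    if sigma_h == 0:
        lower = upper = half_up_int(point)
    if floor_at_zero:
        lower = max(0, lower)
    return PredictionInterval(h=h, point=point, c=c, sigma_h=sigma_h,
                              lower=lower, upper=upper)


def weekly_interval_table(points: Sequence[float], c: float, sigma_h: float,
                          rounding: str = "floor",
                          floor_at_zero: bool = False,
                          ) -> tuple[list[PredictionInterval], float]:
    """Per-day intervals for a 7-point weekly forecast plus the weekly mean.

    The mean of the 7 points is reported to one decimal (half-up).
    """
    if len(points) != 7:
        raise ArityError(f"weekly forecast needs 7 points, got {len(points)}")
    table = [prediction_interval(p, c, sigma_h, h=i + 1, rounding=rounding,
                                 floor_at_zero=floor_at_zero)
             for i, p in enumerate(points)]
    mean_point = round_half_up(float(np.mean(points)), 1)
    return table, mean_point
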