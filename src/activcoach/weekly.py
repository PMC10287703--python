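"""Weekly performance statistics.

For each 7-day week the pipeline computes:

* the weekly means of the five activity features (sedentary, LPA, MPA, VPA
  seconds and steps);
* the activity pattern vector APV — the 7 daily level codes;
* the similarity score ``SC = ΣAPV − ΣGS`` against the goal-score vector GS
  (SC >= 0 means the weekly goal was achieved);
* the performance score ``S = Σ_d level_d × weight(level_d)`` with weights
  {0, 2, 4, 6, 8} = 2×level, so S = 2·Σ level² and 0 <= S <= 224;
* the weekly mean score ``mean_S = S / 7`` displayed to one decimal
  (half-up);
* the cumulative deviation: the population SD of the one-decimal mean-S
  values of all weeks so far, with its error SD/√n (both one decimal).

The deviation list is cumulative from week 1, and it holds the *displayed*
(one-decimal) mean-S values — the convention that reproduces published
worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rounding import round_half_up
from .errors import ArityError, DomainError, InsufficientDataError
from .levels import ActivityLevel, build_apv
from .records import DailyActivityRecord, GoalProfile


@dataclass
class WeeklySummary:
    week_id: int
    mean_sedentary_s: float
    mean_lpa_s: float
    mean_mpa_s: float
    mean_vpa_s: float
    mean_steps: float
    apv: list[int]
    gs: list[int]
    sc: int
    s_total: int
    mean_s: float
    sd: float
    sd_error: float
    # raw auxiliary totals used by the weekly rules
    total_steps: int = 0
    total_mpa_min: float = 0.0
    total_vpa_min: float = 0.0
    total_sedentary_s: int = 0
    total_sleep_min: float | None = None


def weekly_feature_means(
        week: Sequence[DailyActivityRecord]) -> dict[str, float]:
    """Arithmetic means of the five activity features over a 7-day week."""
    if len(week) != 7:
        raise ArityError(f"a week has 7 records, got {len(week)}")
    return {
        "sedentary_s": float(np.mean([r.sedentary_s for r in week])),
        "lpa_s": float(np.mean([r.lpa_s for r in week])),
        "mpa_s": float(np.mean([r.mpa_s for r in week])),
        "vpa_s": float(np.mean([r.vpa_s for r in week])),
        "steps": float(np.mean([r.steps for r in week])),
    }


def similarity_score(apv: Sequence[int], gs: Sequence[int]) -> int:
    """SC = ΣAPV − ΣGS; non-negative means the weekly goal was achieved."""
    if len(apv) != 7 or len(gs) != 7:
        raise ArityError("apv and gs must both have length 7")
    return int(sum(apv) - sum(gs))


def performance_score(apv: Sequence[int]) -> int:
    """S = Σ_d level_d × weight_point(level_d), weights {0, 2, 4, 6, 8}."""
    for lvl in apv:
        if not 0 <= lvl <= 4:
            raise DomainError(f"level {lvl} outside 0-4")
    return int(sum(lvl * ActivityLevel(lvl).weight_point for lvl in apv))


def mean_performance(s_total: int) -> float:
    """Weekly mean score S/7, displayed to one decimal (half-up)."""
    if s_total < 0:
        raise DomainError("s_total must be non-negative")
    return round_half_up(s_total / 7.0, 1)


def cumulative_deviation(
        mean_s_history: Sequence[float]) -> tuple[float, float]:
    """(SD, error) of the weekly mean-S list so far, both to one decimal.

    SD is the population standard deviation of the list; error is SD/√n.
    """
    if len(mean_s_history) == 0:
        raise InsufficientDataError("mean_s_history is empty")
    arr = np.asarray(mean_s_history, dtype=float)
    sd = float(np.std(arr, ddof=0))
    err = sd / np.sqrt(arr.size)
    return round_half_up(sd, 1), round_half_up(err, 1)


def summarize_week(week: Sequence[DailyActivityRecord], goal: GoalProfile,
                   week_id: int,
                   mean_s_history: Sequence[float] = ()) -> WeeklySummary:
    """Build the full weekly summary row.

    ``mean_s_history`` holds the displayed mean-S values of the *previous*
    weeks; this week's value is appended before the cumulative deviation is
    computed.
    """
    means = weekly_feature_means(week)
    apv = build_apv(week)
    gs = list(goal.weekly_goal_vector)
    sc = similarity_score(apv, gs)
    s_total = performance_score(apv)
    mean_s = mean_performance(s_total)
    sd, err = cumulative_deviation(list(mean_s_history) + [mean_s])
    sleeps = [r.sleep_minutes for r in week]
    total_sleep = (float(sum(s for s in sleeps if s is not None))
                   if any(s is not None for s in sleeps) else None)
    return WeeklySummary(
        week_id=week_id,
        mean_sedentary_s=means["sedentary_s"], mean_lpa_s=means["lpa_s"],
        mean_mpa_s=means["mpa_s"], mean_vpa_s=means["vpa_s"],
        mean_steps=means["steps"],
        apv=apv, gs=gs, sc=sc, s_total=s_total, mean_s=mean_s,
        sd=sd, sd_error=err,
        total_steps=int(sum(r.steps for r in week)),
        total_mpa_min=float(sum(r.mpa_s for r in week)) / 60.0,
        total_vpa_min=float(sum(r.vpa_s for r in week)) / 60.0,
        total_sedentary_s=int(sum(r.sedentary_s for r in week)),
        total_sleep_min=total_sleep,
    )
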