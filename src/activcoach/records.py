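"""Domain record types for wearable activity data.

The minute-level record mirrors the native output of a hip-worn tri-axial
activity sensor that splits every minute of wear time into a 60-second budget
of postures/intensities (sedentary, standing, weight-bearing, and low /
moderate / vigorous physical activity) and reports a per-minute activity
intensity count (IMA) plus a step count.  The daily record is the calendar-day
aggregate the downstream models consume.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .errors import ArityError, DomainError

MINUTE_BUDGET_S = 60

#: Canonical CSV header of the minute-level sensor export.
MOX_COLUMNS = (
    "Date",
    "Time",
    "UploadStatus",
    "IMA",
    "WeightBearing",
    "Sedentary",
    "Standing",
    "LPA",
    "MPA",
    "VPA",
    "Steps",
)

DAILY_COLUMNS = ("date", "steps", "sedentary_s", "lpa_s", "mpa_s", "vpa_s")


@dataclass(frozen=True)
class MinuteActivityRecord:
    """One minute of sensor wear time.

    The six second-valued fields partition the minute:
    ``sedentary_s + standing_s + weight_bearing_s + lpa_s + mpa_s + vpa_s``
    should equal 60.  Budget violations are reported as warnings at read time
    (sensor glitches occur in practice), not constructor errors; use
    :meth:`budget_s` / :meth:`is_budget_consistent` to audit.
    """

    date: dt.date
    time: dt.time
    upload_status: str
    ima: int
    weight_bearing_s: int
    sedentary_s: int
    standing_s: int
    lpa_s: int
    mpa_s: int
    vpa_s: int
    steps: int

    def __post_init__(self) -> None:
        for name in ("weight_bearing_s", "sedentary_s", "standing_s",
                     "lpa_s", "mpa_s", "vpa_s"):
            v = getattr(self, name)
            if not 0 <= v <= MINUTE_BUDGET_S:
                raise DomainError(f"{name}={v} outside [0, {MINUTE_BUDGET_S}]")
        if self.ima < 0:
            raise DomainError(f"ima={self.ima} must be non-negative")
        if self.steps < 0:
            raise DomainError(f"steps={self.steps} must be non-negative")

    @property
    def timestamp(self) -> dt.datetime:
        return dt.datetime.combine(self.date, self.time)

    def budget_s(self) -> int:
        return (self.sedentary_s + self.standing_s + self.weight_bearing_s
                + self.lpa_s + self.mpa_s + self.vpa_s)

    def is_budget_consistent(self) -> bool:
        return self.budget_s() == MINUTE_BUDGET_S

    @property
    def upload_flag_known(self) -> bool:
        """Whether the upload flag carries one of the documented values H/L."""
        return self.upload_status in ("H", "L")


@dataclass(frozen=True)
class DailyActivityRecord:
    """Calendar-day totals of steps and activity seconds.

    ``sleep_minutes`` is optional: the minute-level sensor records no sleep,
    while daily smartwatch exports may provide it.
    """

    date: dt.date
    steps: int
    sedentary_s: int
    lpa_s: int
    mpa_s: int
    vpa_s: int
    sleep_minutes: float | None = None

    def __post_init__(self) -> None:
        for name in ("steps", "sedentary_s", "lpa_s", "mpa_s", "vpa_s"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.sleep_minutes is not None and self.sleep_minutes < 0:
            raise DomainError("sleep_minutes must be non-negative")

    @property
    def mpa_min(self) -> float:
        return self.mpa_s / 60.0

    @property
    def vpa_min(self) -> float:
        return self.vpa_s / 60.0


@dataclass
class GoalProfile:
    """Daily and weekly activity targets.

    Defaults follow the WHO adult guidance: 150 minutes of moderate activity
    per week (one vigorous minute counting as two moderate minutes, hence the
    vigorous goal is half the moderate one), a popular 10 000 steps/day
    walking target, at most 8 sedentary hours and 8 sleep hours per day, and a
    daily goal score of 3 (the "medium physical active" level).
    """

    daily_step_goal: int = 10_000
    weekly_step_goal: int = 70_000
    daily_mpa_goal_min: float = 21.45
    daily_vpa_goal_min: float = 10.7
    weekly_mpa_goal_min: float = 150.0
    weekly_vpa_goal_min: float = 75.0
    daily_sedentary_goal_s: int = 8 * 3600
    daily_sleep_goal_h: float = 8.0
    daily_goal_score: int = 3
    weekly_goal_vector: list[int] = field(default_factory=lambda: [3] * 7)

    def __post_init__(self) -> None:
        if len(self.weekly_goal_vector) != 7:
            raise ArityError("weekly_goal_vector must have length 7")
        for name in ("daily_step_goal", "weekly_step_goal", "daily_mpa_goal_min",
                     "daily_vpa_goal_min", "weekly_mpa_goal_min",
                     "weekly_vpa_goal_min", "daily_sedentary_goal_s",
                     "daily_sleep_goal_h"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def weekly_sedentary_goal_s(self) -> int:
        return 7 * self.daily_sedentary_goal_s

    @property
    def weekly_sleep_goal_h(self) -> float:
        return 7 * self.daily_sleep_goal_h


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the shape of a real sensor study: 16 adults wearing the
    device for 34 days, full 1440-minute days, and a target distribution over
    the five daily activity levels skewed toward the sedentary end, as is
    typical for adult free-living cohorts.
    """

    n_participants: int = 16
    n_days: int = 34
    seed: int = 0
    #: target share of days at each activity level 0-4
    activity_mix: list[float] = field(
        default_factory=lambda: [0.35, 0.25, 0.20, 0.12, 0.08])
    minutes_per_day: int = 1440
    #: mean low-activity (walking-about) minutes per day
    lpa_minutes_mean: float = 60.0
    #: relative sd of the per-day step target inside its level band
    step_noise: float = 0.1
    #: probability that a minute's IMA is drawn from a neighbouring band
    ima_band_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_days <= 0:
            raise DomainError("n_participants and n_days must be positive")
        if self.n_days < 14:
            raise DomainError(
                "n_days must be >= 14 (two-week cold-start window)")
        if len(self.activity_mix) != 5:
            raise ArityError("activity_mix needs one weight per level 0-4")
        if any(w < 0 for w in self.activity_mix):
            raise DomainError("activity_mix weights must be non-negative")
        if abs(sum(self.activity_mix) - 1.0) > 1e-9:
            raise DomainError("activity_mix weights must sum to 1")
        if not 0 <= self.ima_band_noise < 1:
            raise DomainError("ima_band_noise must lie in [0, 1)")
        if self.minutes_per_day < 120 or self.minutes_per_day > 1440:
            raise DomainError("minutes_per_day must lie in [120, 1440]")
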