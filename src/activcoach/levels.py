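"""Deterministic daily activity-level classification (WHO-derived rules).

A day is scored 0-4:

====  ======================  ==============================  ==================
code  label                   step-band disjunct              weekly ME disjunct
====  ======================  ==============================  ==================
0     Sedentary               steps < 5000                    (none)
1     Low physical active     4999 < steps < 7500             90 <= ME < 210
2     Active                  7499 < steps < 10000            210 <= ME < 300
3     Medium physical active  9999 < steps < 12500            300 <= ME < 360
4     High physical active    steps > 12499                   ME >= 360
====  ======================  ==============================  ==================

where ME is the weekly moderate-equivalent minute volume extrapolated from the
day, ``(2*vpa_min + mpa_min) * 7`` (one vigorous minute counts as two moderate
minutes), and the ME disjuncts apply only when ``steps > 4999``.  The two
disjunct families overlap; when several levels match, the highest wins, which
keeps the classifier total, deterministic, and monotone in both steps and ME.
Each level carries a weight point equal to twice its code.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

from .errors import ArityError, DomainError
from .records import DailyActivityRecord


class ActivityLevel(IntEnum):
    SEDENTARY = 0
    LOW_ACTIVE = 1
    ACTIVE = 2
    MEDIUM_ACTIVE = 3
    HIGH_ACTIVE = 4

    @property
    def label(self) -> str:
        return _LABELS[self.value]

    @property
    def weight_point(self) -> int:
        """Non-negative weight point used by the performance score (2 x code)."""
        return 2 * self.value


_LABELS = {
    0: "Sedentary",
    1: "Low physical active",
    2: "Active",
    3: "Medium physical active",
    4: "High physical active",
}


def moderate_equivalent_weekly(mpa_min: float, vpa_min: float) -> float:
    """Weekly moderate-equivalent minutes from one day: (2*VPA + MPA) * 7."""
    if mpa_min < 0 or vpa_min < 0:
        raise DomainError("activity minutes must be non-negative")
    return (2.0 * vpa_min + mpa_min) * 7.0


def classify_day(steps: float, mpa_min: float = 0.0,
                 vpa_min: float = 0.0) -> ActivityLevel:
    """Classify one day; highest matching level wins.

    ``mpa_min``/``vpa_min`` are the day's moderate/vigorous minutes (fractions
    kept; no rounding before threshold comparison).
    """
    if steps < 0:
        raise DomainError("steps must be non-negative")
    me = moderate_equivalent_weekly(mpa_min, vpa_min)
    active = steps > 4999
    # evaluated from level 4 down; first match wins
    if (active and me >= 360) or steps > 12_499:
        return ActivityLevel.HIGH_ACTIVE
    if (active and 300 <= me < 360) or (9999 < steps < 12_500):
        return ActivityLevel.MEDIUM_ACTIVE
    if (active and 210 <= me < 300) or (7499 < steps < 10_000):
        return ActivityLevel.ACTIVE
    if (active and 90 <= me < 210) or (4999 < steps < 7500):
        return ActivityLevel.LOW_ACTIVE
    # sedentary rule: steps < 5000 (the LPA >= 0 conjunct is vacuous)
    return ActivityLevel.SEDENTARY


def classify_record(record: DailyActivityRecord) -> ActivityLevel:
    """Classify a daily record, converting second totals to minutes."""
    return classify_day(record.steps, record.mpa_s / 60.0, record.vpa_s / 60.0)


# per-minute activity-type bands over the sensor's intensity count (IMA):
# LPA [0, 400], MPA [401, 800], VPA [801, inf)
IMA_BANDS = {"LPA": (0, 400), "MPA": (401, 800), "VPA": (801, None)}


@dataclass(frozen=True)
class ActivityTypeBand:
    type: str
    ima_low: int
    ima_high: int | None  # None = unbounded


def classify_ima(ima: int) -> str:
    """Band a per-minute intensity count into LPA / MPA / VPA."""
    if ima < 0:
        raise DomainError("ima must be non-negative")
    if ima <= 400:
        return "LPA"
    if ima <= 800:
        return "MPA"
    return "VPA"


def build_apv(week: Sequence[DailyActivityRecord]) -> list[int]:
    """Activity pattern vector: the 7 daily level codes of one week, in order.

    Requires exactly 7 records on consecutive calendar dates.
    """
    if len(week) != 7:
        raise ArityError(f"a week has 7 records, got {len(week)}")
    for prev, cur in zip(week, week[1:]):
        if (cur.date - prev.date).days != 1:
            raise ArityError(
                f"dates not consecutive: {prev.date} -> {cur.date}")
    return [int(classify_record(r)) for r in week]
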