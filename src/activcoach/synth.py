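"""Seeded synthetic cohort generator.

Emulates minute-level records from a hip-worn activity sensor so that every
downstream stage (classification, forecasting, weekly statistics, the rule
engine) is testable without any real recording.  The generative model, per
participant-day:

1. draw a target activity level 0-4 from ``spec.activity_mix``;
2. draw a daily step target uniformly inside that level's step band (with
   multiplicative noise ``spec.step_noise``, clipped back into the band) and a
   moderate/vigorous minute volume whose weekly moderate-equivalent lies in
   the same level's band, so the rule classifier labels the day at the target
   level by construction (the level-from-steps and level-from-minutes
   disjuncts agree);
3. lay out a minute schedule: vigorous and moderate minutes first, a
   low-activity (ambulation) block, and the remainder sedentary; each active
   minute gives its dominant type 45-60 s and splits the rest between
   sedentary/standing/weight-bearing so that every minute's second fields sum
   to exactly 60;
4. draw each minute's intensity count (IMA) from the band of its dominant
   activity type (sedentary minutes draw from the bottom of the low band);
   with probability ``spec.ima_band_noise`` the draw spills into a
   neighbouring band;
5. distribute the daily step target multinomially over the active minutes,
   weighted by intensity, so daily totals are exact.

All randomness flows from a single ``numpy`` generator seeded with
``spec.seed``: identical specs give byte-identical cohorts.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from .records import CohortSpec, MinuteActivityRecord

# inclusive daily step bands per level (upper edge of level 4 is a practical cap)
STEP_BANDS = {
    0: (500, 4999),
    1: (5000, 7499),
    2: (7500, 9999),
    3: (10_000, 12_499),
    4: (12_500, 16_000),
}
# weekly moderate-equivalent minute bands per level
ME_BANDS = {
    0: (0.0, 89.0),
    1: (90.0, 209.0),
    2: (210.0, 299.0),
    3: (300.0, 359.0),
    4: (360.0, 480.0),
}
# IMA draw ranges by dominant minute type
_IMA_RANGES = {"sedentary": (0, 100), "LPA": (0, 400),
               "MPA": (401, 800), "VPA": (801, 1200)}
_NEIGHBOUR = {"LPA": "MPA", "MPA": "VPA", "VPA": "MPA", "sedentary": "LPA"}


def _day_minutes(rng: np.random.Generator, spec: CohortSpec, date: dt.date,
                 level: int) -> list[MinuteActivityRecord]:
    n_min = spec.minutes_per_day

    lo, hi = STEP_BANDS[level]
    steps_target = int(np.clip(
        rng.integers(lo, hi + 1) * (1.0 + spec.step_noise * rng.standard_normal()),
        lo, hi))

    me_lo, me_hi = ME_BANDS[level]
    me_weekly = rng.uniform(me_lo, me_hi)
    me_daily = me_weekly / 7.0  # minutes of 2*vpa + mpa per day
    vpa_share = rng.uniform(0.0, 0.3)
    vpa_minutes = int(round(me_daily * vpa_share / 2.0))
    mpa_minutes = int(round(me_daily * (1.0 - vpa_share)))
    lpa_minutes = int(np.clip(rng.normal(spec.lpa_minutes_mean,
                                         spec.lpa_minutes_mean / 4.0), 10, 240))
    active = vpa_minutes + mpa_minutes + lpa_minutes
    if active > n_min - 10:  # keep at least a sliver of sedentary time
        lpa_minutes = max(10, n_min - 10 - vpa_minutes - mpa_minutes)
        active = vpa_minutes + mpa_minutes + lpa_minutes

    # dominant type per minute: 0=sedentary, 1=LPA, 2=MPA, 3=VPA
    kinds = np.repeat([3, 2, 1, 0],
                      [vpa_minutes, mpa_minutes, lpa_minutes, n_min - active])
    kinds = kinds[rng.permutation(n_min)]
    kind_names = np.array(["sedentary", "LPA", "MPA", "VPA"])

    dom_seconds = rng.integers(45, 61, size=n_min)
    leftovers = 60 - dom_seconds
    # split each minute's leftover seconds across sedentary/standing/weight-bearing
    split = rng.dirichlet([1.0, 1.0, 1.0], size=n_min)
    rest_sed = np.floor(split[:, 0] * leftovers).astype(int)
    rest_stand = np.floor(split[:, 1] * leftovers).astype(int)
    rest_wb = leftovers - rest_sed - rest_stand

    sed = rest_sed + np.where(kinds == 0, dom_seconds, 0)
    stand, wb = rest_stand, rest_wb
    lpa = np.where(kinds == 1, dom_seconds, 0)
    mpa = np.where(kinds == 2, dom_seconds, 0)
    vpa = np.where(kinds == 3, dom_seconds, 0)

    bands = kind_names[kinds]
    if spec.ima_band_noise:
        spill = rng.random(n_min) < spec.ima_band_noise
        bands = np.where(spill, np.vectorize(_NEIGHBOUR.get)(bands), bands)
    ima = np.zeros(n_min, int)
    for name, (lo_i, hi_i) in _IMA_RANGES.items():
        mask = bands == name
        if mask.any():
            ima[mask] = rng.integers(lo_i, hi_i + 1, size=int(mask.sum()))

    weights = lpa * 1.0 + mpa * 2.5 + vpa * 4.0
    if weights.sum() == 0:
        weights = np.ones(n_min)
    steps = rng.multinomial(steps_target, weights / weights.sum())

    return [MinuteActivityRecord(
        date=date, time=dt.time(i // 60, i % 60), upload_status="H",
        ima=int(ima[i]), weight_bearing_s=int(wb[i]), sedentary_s=int(sed[i]),
        standing_s=int(stand[i]), lpa_s=int(lpa[i]), mpa_s=int(mpa[i]),
        vpa_s=int(vpa[i]), steps=int(steps[i])) for i in range(n_min)]


def synthesize_cohort(
        spec: CohortSpec,
        start_date: dt.date = dt.date(2023, 1, 2),
) -> dict[str, list[MinuteActivityRecord]]:
    """Generate ``spec.n_participants`` minute-record sequences.

    Returns a mapping ``{"P-1": [...], "P-2": [...], ...}`` of chronological
    minute records, ``spec.n_days`` consecutive days each.  Deterministic for
    a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    cohort: dict[str, list[MinuteActivityRecord]] = {}
    for p in range(spec.n_participants):
        levels = rng.choice(5, size=spec.n_days, p=spec.activity_mix)
        minutes: list[MinuteActivityRecord] = []
        for d in range(spec.n_days):
            date = start_date + dt.timedelta(days=d)
            minutes.extend(_day_minutes(rng, spec, date, int(levels[d])))
        cohort[f"P-{p + 1}"] = minutes
    return cohort
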