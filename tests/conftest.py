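import datetime as dt

import pytest

from activcoach.records import CohortSpec, DailyActivityRecord, GoalProfile
from activcoach.synth import synthesize_cohort


@pytest.fixture(scope="session")
def goals() -> GoalProfile:
    return GoalProfile()


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    # shortened days keep the suite fast without changing any invariant
    return CohortSpec(n_participants=2, n_days=14, seed=7, minutes_per_day=480)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return synthesize_cohort(small_spec)


def make_week(steps_per_day, start=dt.date(2023, 1, 2), mpa_s=0, vpa_s=0,
              sedentary_s=20_000):
    """Seven consecutive daily records with the given step counts."""
    return [DailyActivityRecord(
        date=start + dt.timedelta(days=i), steps=int(s),
        sedentary_s=sedentary_s, lpa_s=3600, mpa_s=mpa_s, vpa_s=vpa_s)
        for i, s in enumerate(steps_per_day)]
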