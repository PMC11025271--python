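"""Shared builders for hand-constructed actigraphy fixtures.

Everything is generated programmatically: epoch series are assembled from
(count, n_epochs) run specifications and diaries from clock-hour tuples, so
threshold-bracketing fixtures state their structure explicitly at the call
site.
"""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import numpy as np
import pytest

from actiprofile.io import DiaryDay, EpochSeries

START_DATE = date(2024, 3, 4)  # a Monday
EPOCH = 30
EPD = 86_400 // EPOCH


def dt(day_offset: float, hours: float) -> datetime:
    """Clock instant: midnight of START_DATE + day_offset days + hours."""
    return datetime.combine(START_DATE, time()) + timedelta(days=day_offset, hours=hours)


def make_series(counts, start=None, subject_id="s1") -> EpochSeries:
    return EpochSeries(
        subject_id=subject_id,
        start=start or dt(0, 0),
        epoch_length=EPOCH,
        counts=np.asarray(counts, dtype=float),
        flags=None,
    )


def flat_days(n_days: int, day_value: float = 100.0, sleep=(21.0, 7.0)) -> np.ndarray:
    """Counts for n whole days: constant by day, quiet nights with a small
    movement burst every 30 minutes (so rest is recorded but no zero run ever
    reaches the 120-min sleep rule)."""
    onset, offset = sleep
    n = n_days * EPD
    counts = np.full(n, day_value)
    clock = (np.arange(n) * EPOCH / 3600.0) % 24.0
    night = (clock < offset) | (clock >= onset)
    counts[night] = 0.0
    counts[night & (np.arange(n) % 60 == 0)] = 20.0
    return counts


def diary_day(day: int, onset: float = 21.0, offset: float = 7.0,
              naps=(), removals=(), sedentary=()) -> DiaryDay:
    """Diary row for recorded day ``day``: night [onset, offset(+1d)], events
    given as (start_hour, end_hour) clock tuples of that day."""
    def iv(pairs):
        return [(dt(day, a), dt(day, b)) for a, b in pairs]

    return DiaryDay(
        date=START_DATE + timedelta(days=day),
        sleep_onset=dt(day, onset),
        sleep_offset=dt(day + 1, offset),
        naps=iv(naps),
        removals=iv(removals),
        sedentary=iv(sedentary),
    )


def standard_diary(n_days: int, onset: float = 21.0, offset: float = 7.0,
                   **per_day) -> list[DiaryDay]:
    """Diary covering the night before day 0 through day n_days - 1.

    ``per_day`` maps ``removals_<d>``/``naps_<d>``/``sedentary_<d>`` to event
    tuples for recorded day d.
    """
    days = [DiaryDay(
        date=START_DATE - timedelta(days=1),
        sleep_onset=dt(-1, onset),
        sleep_offset=dt(0, offset),
    )]
    for d in range(n_days):
        days.append(diary_day(
            d, onset, offset,
            naps=per_day.get(f"naps_{d}", ()),
            removals=per_day.get(f"removals_{d}", ()),
            sedentary=per_day.get(f"sedentary_{d}", ()),
        ))
    return days


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)
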