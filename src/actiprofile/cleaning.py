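"""Diary-aware cleaning of epoch-level actigraphy.

The protocol detects device removal, imputes the removed periods from donor
days and excludes invalid days and under-sampled subjects:

1. align diary intervals to the epoch grid;
2. detect removal as (a) diary-recorded removal intervals, (b) runs of
   zero-count epochs lasting at least 10 minutes whose every epoch is
   wake-labelled (not sedentary, nap or sleep), and (c) runs of zero-count
   epochs lasting at least 120 minutes lying entirely within sleep or naps;
3. screen for systematic device error (no rest recorded across a 24-h
   window);
4. classify day validity: a day is invalid when at least 3 hours of removal
   fall on it, when no diary row exists for it, when it is systematic-error
   flagged, or when the recording covers it only partially;
5. impute every removed epoch on a valid day with the mean count at the same
   clock time over the other valid days (donor days);
6. include a subject when at least 5 valid days remain.

"Inactivity" means a count of exactly zero: Actiwatch counts are non-negative
integers and an un-worn device accumulates none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from .io import (
    FLAG_DETECTED_REMOVAL,
    FLAG_DIARY_REMOVAL,
    FLAG_IMPUTED,
    SECONDS_PER_DAY,
    STATE_DIARY_REMOVAL,
    STATE_NAP,
    STATE_NO_DIARY,
    STATE_SEDENTARY,
    STATE_SLEEP,
    STATE_WAKE,
    DiaryDay,
    EpochSeries,
    ValidationError,
    align_to_epochs,
)

logger = logging.getLogger("actiprofile.cleaning")

__all__ = [
    "CleaningConfig",
    "RemovalInterval",
    "DayReport",
    "UnimputableError",
    "detect_removal_intervals",
    "detect_systematic_error",
    "classify_day_validity",
    "impute_removals",
    "apply_protocol",
    "include_subject",
    "merge_intervals",
]


@dataclass
class CleaningConfig:
    """Thresholds of the cleaning protocol, in the units the rules are stated in."""

    wake_inactivity_min: float = 10.0       # minutes of wake zero-run => removal
    sleep_inactivity_min: float = 120.0     # minutes of sleep zero-run => removal
    day_exclusion_hours: float = 3.0        # removal per day => day invalid
    min_valid_days: int = 5                 # valid days required per subject
    systematic_error_window_hours: float = 24.0
    systematic_error_rest_threshold: float = 0.0

    def __post_init__(self) -> None:
        if min(self.wake_inactivity_min, self.sleep_inactivity_min,
               self.day_exclusion_hours, self.systematic_error_window_hours) <= 0:
            raise ValidationError("cleaning thresholds must be positive")
        if self.min_valid_days < 1:
            raise ValidationError("min_valid_days must be at least 1")


@dataclass(frozen=True)
class RemovalInterval:
    """Half-open epoch index range attributed to device removal."""

    start: int
    end: int
    source: str  # diary | wake_rule | sleep_rule (merged: '+'-joined)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("removal interval must have positive length")

    @property
    def n_epochs(self) -> int:
        return self.end - self.start


REASON_REMOVAL = "removal_ge_3h"
REASON_NO_DIARY = "no_diary"
REASON_SYSTEMATIC = "systematic_error"
REASON_PARTIAL = "partial_day"


@dataclass
class DayReport:
    date: date
    removal_minutes: float
    valid: bool
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.valid == (self.exclusion_reason is not None):
            raise ValidationError("valid XOR exclusion_reason must hold")


class UnimputableError(RuntimeError):
    """A removed clock epoch has no donor day to impute from."""


# ---------------------------------------------------------------------------
# helpers


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open [start, end) runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def merge_intervals(intervals: Sequence[RemovalInterval]) -> list[RemovalInterval]:
    """Merge overlapping or touching intervals; sources are '+'-joined."""
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda r: (r.start, r.end))
    merged = [ordered[0]]
    for nxt in ordered[1:]:
        last = merged[-1]
        if nxt.start <= last.end:
            sources = list(dict.fromkeys(last.source.split("+") + nxt.source.split("+")))
            merged[-1] = RemovalInterval(last.start, max(last.end, nxt.end), "+".join(sources))
        else:
            merged.append(nxt)
    return merged


def _removal_mask(n: int, removals: Sequence[RemovalInterval]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for r in removals:
        mask[r.start:r.end] = True
    return mask


def _day_bounds(series: EpochSeries) -> list[tuple[date, int, int]]:
    """Calendar days intersecting the recording as (day, first_epoch, last_epoch+1)."""
    epd = series.epochs_per_day
    midnight = datetime.combine(series.start.date(), time())
    start_off = int((series.start - midnight).total_seconds()) // series.epoch_length
    out = []
    k = 0
    while True:
        i0 = k * epd - start_off
        i1 = i0 + epd
        if i0 >= series.n_epochs:
            break
        out.append((series.start.date() + timedelta(days=k), max(i0, 0), min(i1, series.n_epochs)))
        k += 1
    return out


# ---------------------------------------------------------------------------
# detection


def detect_removal_intervals(
    series: EpochSeries,
    states: np.ndarray,
    config: CleaningConfig | None = None,
) -> list[RemovalInterval]:
    """Merged union of diary-recorded and rule-detected removal intervals.

    The wake rule requires every epoch of a zero run to be wake-labelled, so
    a single sedentary epoch splits the run and each wake-only remainder must
    clear the 10-minute threshold by itself.  Naps count as sleep for the
    120-minute rule.  Zero runs on ``no_diary`` epochs are never rule-detected
    (the whole day is invalidated instead).
    """
    config = config or CleaningConfig()
    zero = series.counts == 0
    wake_epochs = int(np.ceil(config.wake_inactivity_min * 60 / series.epoch_length))
    sleep_epochs = int(np.ceil(config.sleep_inactivity_min * 60 / series.epoch_length))

    found: list[RemovalInterval] = []
    for i0, i1 in _runs(states == STATE_DIARY_REMOVAL):
        found.append(RemovalInterval(i0, i1, "diary"))
    for i0, i1 in _runs(zero & (states == STATE_WAKE)):
        if i1 - i0 >= wake_epochs:
            found.append(RemovalInterval(i0, i1, "wake_rule"))
            logger.info("wake_rule removal: epochs %d-%d (%.1f min)", i0, i1,
                        (i1 - i0) * series.epoch_length / 60)
    asleep = (states == STATE_SLEEP) | (states == STATE_NAP)
    for i0, i1 in _runs(zero & asleep):
        if i1 - i0 >= sleep_epochs:
            found.append(RemovalInterval(i0, i1, "sleep_rule"))
            logger.info("sleep_rule removal: epochs %d-%d (%.1f min)", i0, i1,
                        (i1 - i0) * series.epoch_length / 60)
    return merge_intervals(found)


def detect_systematic_error(
    series: EpochSeries,
    config: CleaningConfig | None = None,
) -> list[date]:
    """Calendar days inside any 24-h window that records no rest at all.

    Rest means a count at or below ``systematic_error_rest_threshold``
    (default 0).  A recording shorter than the window with no rest anywhere
    flags every covered day.
    """
    config = config or CleaningConfig()
    window = int(round(config.systematic_error_window_hours * 3600 / series.epoch_length))
    rest = series.counts <= config.systematic_error_rest_threshold
    bounds = _day_bounds(series)

    flagged: set[date] = set()
    if series.n_epochs < window:
        if not rest.any():
            flagged.update(day for day, _, _ in bounds)
    else:
        csum = np.concatenate(([0], np.cumsum(rest)))
        in_window = csum[window:] - csum[:-window]  # rest epochs in [i, i+window)
        for i in np.flatnonzero(in_window == 0):
            lo, hi = int(i), int(i) + window
            for day, d0, d1 in bounds:
                if d0 < hi and d1 > lo:
                    flagged.add(day)
    for day in sorted(flagged):
        logger.info("systematic error flagged on %s", day)
    return sorted(flagged)


def classify_day_validity(
    series: EpochSeries,
    removals: Sequence[RemovalInterval],
    diary: Sequence[DiaryDay],
    systematic_flags: Sequence[date] = (),
    config: CleaningConfig | None = None,
) -> list[DayReport]:
    """One report per calendar day intersecting the recording."""
    config = config or CleaningConfig()
    epd = series.epochs_per_day
    rem_mask = _removal_mask(series.n_epochs, removals)
    diary_dates = {d.date for d in diary}
    flagged = set(systematic_flags)
    limit_min = config.day_exclusion_hours * 60

    reports = []
    for day, i0, i1 in _day_bounds(series):
        removal_minutes = float(rem_mask[i0:i1].sum()) * series.epoch_length / 60
        reason = None
        if i1 - i0 < epd:
            reason = REASON_PARTIAL
        elif removal_minutes >= limit_min:
            reason = REASON_REMOVAL
        elif day not in diary_dates:
            reason = REASON_NO_DIARY
        elif day in flagged:
            reason = REASON_SYSTEMATIC
        if reason:
            logger.info("day %s excluded: %s (removal %.1f min)", day, reason, removal_minutes)
        reports.append(DayReport(day, removal_minutes, reason is None, reason))
    return reports


def impute_removals(
    series: EpochSeries,
    removals: Sequence[RemovalInterval],
    day_reports: Sequence[DayReport],
) -> EpochSeries:
    """Replace removed epochs on valid days by the donor-day mean at the same clock time.

    Donors are epochs at the same clock offset on *other valid days* that are
    themselves neither removed nor missing.  Epochs on invalid days are left
    untouched — those days are dropped downstream.
    """
    out = series.copy()
    rem_mask = _removal_mask(series.n_epochs, removals)
    for r in removals:
        flag = FLAG_DIARY_REMOVAL if "diary" in r.source else FLAG_DETECTED_REMOVAL
        out.flags[r.start:r.end] = flag
    if not rem_mask.any():
        return out

    valid_days = sorted({rep.date for rep in day_reports if rep.valid})
    bounds = _day_bounds(series)
    day_starts = {day: (i0, i1) for day, i0, i1 in bounds}
    epoch_day = np.empty(series.n_epochs, dtype=object)
    for day, i0, i1 in bounds:
        epoch_day[i0:i1] = day

    # clock slot of each epoch (seconds past midnight / epoch_length)
    midnight = datetime.combine(series.start.date(), time())
    start_off = int((series.start - midnight).total_seconds()) // series.epoch_length
    slots = (np.arange(series.n_epochs) + start_off) % series.epochs_per_day

    to_impute = np.flatnonzero(rem_mask & np.array([d in valid_days for d in epoch_day]))
    for i in to_impute:
        slot = slots[i]
        donors = []
        for day in valid_days:
            if day == epoch_day[i]:
                continue
            i0, i1 = day_starts[day]
            j = i0 + (slot - slots[i0]) % series.epochs_per_day
            if i0 <= j < i1 and not rem_mask[j]:
                donors.append(series.counts[j])
        if not donors:
            raise UnimputableError(
                f"no donor days for epoch {i} at {series.timestamp(int(i)):%Y-%m-%d %H:%M:%S}"
            )
        out.counts[i] = float(np.mean(donors))
        out.flags[i] = FLAG_IMPUTED
    return out


def apply_protocol(
    series: EpochSeries,
    diary: Sequence[DiaryDay],
    config: CleaningConfig | None = None,
) -> tuple[EpochSeries, list[DayReport], list[RemovalInterval]]:
    """Run the full protocol and return the cleaned valid-day series.

    The cleaned series stacks the valid days back to back (its ``start`` is
    the first valid day's midnight); per-clock-time averaging downstream only
    needs whole days, not contiguity.
    """
    config = config or CleaningConfig()
    states = align_to_epochs(diary, series)
    removals = detect_removal_intervals(series, states, config)
    flagged = detect_systematic_error(series, config)
    reports = classify_day_validity(series, removals, diary, flagged, config)
    imputed = impute_removals(series, removals, reports)

    valid = [rep.date for rep in reports if rep.valid]
    if valid:
        bounds = {day: (i0, i1) for day, i0, i1 in _day_bounds(series)}
        pieces = [imputed.counts[slice(*bounds[d])] for d in valid]
        flag_pieces = [imputed.flags[slice(*bounds[d])] for d in valid]
        cleaned = EpochSeries(
            subject_id=series.subject_id,
            start=datetime.combine(valid[0], time()),
            epoch_length=series.epoch_length,
            counts=np.concatenate(pieces),
            flags=np.concatenate(flag_pieces),
        )
        cleaned.day_dates = list(valid)  # type: ignore[attr-defined]
    else:
        cleaned = EpochSeries(
            subject_id=series.subject_id,
            start=series.start,
            epoch_length=series.epoch_length,
            counts=np.empty(1) * np.nan,
            flags=None,
        )
        cleaned.counts = np.empty(0)
        cleaned.flags = np.empty(0, dtype="U18")
        cleaned.day_dates = []  # type: ignore[attr-defined]
    return cleaned, reports, removals


def include_subject(
    day_reports: Sequence[DayReport],
    config: CleaningConfig | None = None,
) -> tuple[bool, dict]:
    """Subject-level inclusion: at least ``min_valid_days`` valid days.

    The >=4-weekday / >=1-weekend-day composition is reported as a
    diagnostic only; it was descriptive, not exclusionary, in the protocol
    this reproduces.
    """
    config = config or CleaningConfig()
    valid = [rep.date for rep in day_reports if rep.valid]
    weekdays = sum(1 for d in valid if d.weekday() < 5)
    weekends = len(valid) - weekdays
    diagnostics = {
        "n_valid_days": len(valid),
        "n_weekdays": weekdays,
        "n_weekend_days": weekends,
        "weekday_criterion_met": weekdays >= 4,
        "weekend_criterion_met": weekends >= 1,
        "exclusion_reasons": {
            rep.date.isoformat(): rep.exclusion_reason
            for rep in day_reports if not rep.valid
        },
    }
    included = len(valid) >= config.min_valid_days
    if not included:
        logger.info("subject excluded: %d valid days < %d", len(valid), config.min_valid_days)
    return included, diagnostics
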