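"""Reading, writing and aligning actigraphy inputs.

Three plain-text inputs drive the pipeline, one file (or table) each for

* epoch-level activity counts — one CSV per subject with ``timestamp,count``
  columns on a uniform 30-second grid,
* daily sleep diaries — one row per subject-day recording the night's sleep
  interval, daytime naps, device removals, evening sedentary periods and
  optional morning/evening overactivity ratings,
* subject metadata — group membership, age, sex, mobility and the
  questionnaire overactivity score.

All times are local clock times (naive, no timezone).  The epoch grid is
half-open and left-aligned: the epoch stamped ``t`` covers ``[t, t + 30 s)``.
Diary intervals map onto epochs by any-overlap, so an epoch belongs to an
interval as soon as the two intersect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "EpochSeries",
    "DiaryDay",
    "SubjectMeta",
    "FLAG_OBSERVED",
    "FLAG_DIARY_REMOVAL",
    "FLAG_DETECTED_REMOVAL",
    "FLAG_IMPUTED",
    "STATE_WAKE",
    "STATE_SLEEP",
    "STATE_NAP",
    "STATE_SEDENTARY",
    "STATE_DIARY_REMOVAL",
    "STATE_NO_DIARY",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_diary_csv",
    "write_diary_csv",
    "read_metadata_csv",
    "align_to_epochs",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout (spacing, time syntax)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (negative counts, bad intervals)."""


SECONDS_PER_DAY = 86_400

FLAG_OBSERVED = "observed"
FLAG_DIARY_REMOVAL = "diary_removal"
FLAG_DETECTED_REMOVAL = "detected_removal"
FLAG_IMPUTED = "imputed"

STATE_WAKE = "wake"
STATE_SLEEP = "sleep"
STATE_NAP = "nap"
STATE_SEDENTARY = "sedentary"
STATE_DIARY_REMOVAL = "diary_removal"
STATE_NO_DIARY = "no_diary"


@dataclass
class EpochSeries:
    """Uniformly spaced activity counts for one subject.

    ``counts`` are non-negative and integer-valued as recorded; imputation may
    later introduce non-integer values (flag ``imputed``).  ``flags`` carries a
    per-epoch provenance label.
    """

    subject_id: str
    start: datetime
    epoch_length: int
    counts: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValidationError("counts must be a non-empty 1-d sequence")
        if self.flags is None:
            self.flags = np.full(self.counts.size, FLAG_OBSERVED, dtype="U18")
        else:
            self.flags = np.asarray(self.flags, dtype="U18")
        if self.flags.size != self.counts.size:
            raise ValidationError("flags length must equal counts length")
        if SECONDS_PER_DAY % self.epoch_length:
            raise ValidationError("epoch_length must divide 86400 seconds")
        if np.any(self.counts < 0):
            raise ValidationError("activity counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_length

    def timestamp(self, index: int) -> datetime:
        return self.start + timedelta(seconds=index * self.epoch_length)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=self.n_epochs, freq=pd.Timedelta(seconds=self.epoch_length)
        )

    def epoch_index(self, when: datetime) -> float:
        """Fractional epoch index of a clock instant (may lie outside the series)."""
        return (when - self.start).total_seconds() / self.epoch_length

    def day_of_epoch(self, index: int) -> date:
        return self.timestamp(index).date()

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            subject_id=self.subject_id,
            start=self.start,
            epoch_length=self.epoch_length,
            counts=self.counts.copy(),
            flags=self.flags.copy(),
        )


Interval = tuple[datetime, datetime]


@dataclass
class DiaryDay:
    """One caregiver diary row: the night starting on ``date`` plus daytime events."""

    date: date
    sleep_onset: datetime
    sleep_offset: datetime
    naps: list[Interval] = field(default_factory=list)
    removals: list[Interval] = field(default_factory=list)
    sedentary: list[Interval] = field(default_factory=list)
    am_overactivity: int | None = None
    pm_overactivity: int | None = None

    def __post_init__(self) -> None:
        if self.sleep_offset <= self.sleep_onset:
            raise ValidationError(
                f"{self.date}: sleep_offset must follow sleep_onset"
            )
        for name in ("naps", "removals", "sedentary"):
            _check_intervals(getattr(self, name), f"{self.date}:{name}")
        # naps belong to the waking day preceding this row's night
        for a, b in self.naps:
            if b > self.sleep_onset:
                raise ValidationError(
                    f"{self.date}: nap {a:%H:%M}-{b:%H:%M} overlaps the night"
                )


def _check_intervals(intervals: Sequence[Interval], label: str) -> None:
    for a, b in intervals:
        if b <= a:
            raise ValidationError(f"{label}: interval end {b} not after start {a}")
    ordered = sorted(intervals)
    for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
        if a2 < b1:
            raise ValidationError(f"{label}: overlapping intervals")


@dataclass
class SubjectMeta:
    """Group label, demographics and questionnaire overactivity score."""

    subject_id: str
    group: str
    age: float
    sex: str
    mobility: str  # walks_unaided | not_unaided
    taq_overactivity: int | None
    lockdown_flag: bool = False
    vabs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.taq_overactivity is not None and self.taq_overactivity < 0:
            raise ValidationError("taq_overactivity must be non-negative")


# ---------------------------------------------------------------------------
# epoch CSV


def read_epoch_csv(path: str | Path, epoch_length: int = 30, subject_id: str | None = None) -> EpochSeries:
    """Read a ``timestamp,count`` CSV onto a complete epoch grid.

    Timestamps must be strictly increasing and lie on the grid defined by the
    first timestamp and ``epoch_length``; any missing grid slots are filled
    with count 0 and flag ``observed`` (recognising them as device removal is
    the cleaning stage's job, not the reader's).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if not {"timestamp", "count"}.issubset(frame.columns):
        raise FormatError(f"{path}: expected columns timestamp,count")
    try:
        stamps = pd.to_datetime(frame["timestamp"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from exc
    if stamps.size == 0:
        raise FormatError(f"{path}: empty file")
    if not stamps.is_monotonic_increasing or stamps.duplicated().any():
        raise FormatError(f"{path}: timestamps must be strictly increasing")
    offsets = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy()
    slots = offsets / epoch_length
    if np.any(np.abs(slots - np.round(slots)) * epoch_length > 1.0):
        raise FormatError(f"{path}: non-uniform epoch spacing")
    slots = np.round(slots).astype(int)
    counts_in = frame["count"].to_numpy(dtype=float)
    if np.any(~np.isfinite(counts_in)) or np.any(counts_in < 0):
        raise ValidationError(f"{path}: counts must be finite and non-negative")
    if np.any(np.abs(counts_in - np.round(counts_in)) > 0):
        raise ValidationError(f"{path}: raw counts must be integers")
    n = int(slots[-1]) + 1
    counts = np.zeros(n, dtype=float)
    counts[slots] = counts_in
    return EpochSeries(
        subject_id=subject_id or path.stem,
        start=stamps.iloc[0].to_pydatetime(),
        epoch_length=epoch_length,
        counts=counts,
        flags=np.full(n, FLAG_OBSERVED, dtype="U18"),
    )


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"timestamp": series.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
         "count": series.counts}
    )
    # preserve integer formatting for unimputed data
    if np.all(series.counts == np.round(series.counts)):
        frame["count"] = frame["count"].astype(int)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diary CSV

_DIARY_COLUMNS = [
    "subject_id", "date", "sleep_onset", "sleep_offset",
    "naps", "removals", "sedentary", "am_overactivity", "pm_overactivity",
]


def _parse_clock(token: str, day: date, label: str) -> datetime:
    token = token.strip()
    plus = 0
    if token.endswith("+1d"):
        plus, token = 1, token[:-3]
    try:
        t = datetime.strptime(token, "%H:%M").time()
    except ValueError as exc:
        raise FormatError(f"{label}: unparseable time {token!r}") from exc
    return datetime.combine(day, t) + timedelta(days=plus)


def _parse_interval_list(cell: str | float, day: date, label: str) -> list[Interval]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return []
    out = []
    for chunk in str(cell).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split("-")
        if len(parts) != 2:
            raise FormatError(f"{label}: malformed interval {chunk!r}")
        a = _parse_clock(parts[0], day, label)
        b = _parse_clock(parts[1], day, label)
        out.append((a, b))
    return out


def read_diary_csv(path: str | Path, subject_id: str | None = None) -> list[DiaryDay]:
    """Read diary rows into chronologically ordered :class:`DiaryDay` records.

    When ``subject_id`` is given, only that subject's rows are returned.
    Days absent from the file are simply absent from the result; flagging them
    is the cleaning stage's job.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(_DIARY_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing diary columns {sorted(missing)}")
    if subject_id is not None:
        frame = frame[frame["subject_id"] == subject_id]
    days = []
    for _, row in frame.iterrows():
        label = f"{path}:{row['subject_id']}:{row['date']}"
        try:
            day = pd.Timestamp(row["date"]).date()
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{label}: unparseable date") from exc

        def _rating(col: str) -> int | None:
            if col not in row or pd.isna(row[col]):
                return None
            return int(row[col])

        days.append(
            DiaryDay(
                date=day,
                sleep_onset=_parse_clock(str(row["sleep_onset"]), day, label),
                sleep_offset=_parse_clock(str(row["sleep_offset"]), day, label),
                naps=_parse_interval_list(row.get("naps"), day, label),
                removals=_parse_interval_list(row.get("removals"), day, label),
                sedentary=_parse_interval_list(row.get("sedentary"), day, label),
                am_overactivity=_rating("am_overactivity"),
                pm_overactivity=_rating("pm_overactivity"),
            )
        )
    days.sort(key=lambda d: d.date)
    return days


def _fmt_clock(when: datetime, day: date) -> str:
    suffix = "+1d" if when.date() > day else ""
    return when.strftime("%H:%M") + suffix


def write_diary_csv(rows: Iterable[tuple[str, DiaryDay]], path: str | Path) -> None:
    records = []
    for subject_id, d in rows:
        records.append({
            "subject_id": subject_id,
            "date": d.date.isoformat(),
            "sleep_onset": _fmt_clock(d.sleep_onset, d.date),
            "sleep_offset": _fmt_clock(d.sleep_offset, d.date),
            "naps": ";".join(f"{_fmt_clock(a, d.date)}-{_fmt_clock(b, d.date)}" for a, b in d.naps),
            "removals": ";".join(f"{_fmt_clock(a, d.date)}-{_fmt_clock(b, d.date)}" for a, b in d.removals),
            "sedentary": ";".join(f"{_fmt_clock(a, d.date)}-{_fmt_clock(b, d.date)}" for a, b in d.sedentary),
            "am_overactivity": d.am_overactivity,
            "pm_overactivity": d.pm_overactivity,
        })
    pd.DataFrame(records, columns=_DIARY_COLUMNS).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> list[SubjectMeta]:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    metas = []
    for _, row in frame.iterrows():
        vabs = {c: row[c] for c in frame.columns if c.startswith("vabs_") and pd.notna(row[c])}
        taq = None if pd.isna(row.get("taq_overactivity")) else int(row["taq_overactivity"])
        metas.append(
            SubjectMeta(
                subject_id=row["subject_id"],
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                mobility=str(row["mobility"]),
                taq_overactivity=taq,
                lockdown_flag=bool(row.get("lockdown_flag", False)),
                vabs=vabs,
            )
        )
    return metas


# ---------------------------------------------------------------------------
# diary -> epoch alignment


def _interval_slice(series: EpochSeries, start: datetime, end: datetime) -> slice:
    """Epoch index range intersecting ``[start, end)`` (any-overlap rule)."""
    i0 = math.floor(series.epoch_index(start))
    i1 = math.ceil(series.epoch_index(end))
    return slice(max(i0, 0), min(max(i1, 0), series.n_epochs))


def align_to_epochs(diary: Sequence[DiaryDay], series: EpochSeries) -> np.ndarray:
    """Label every epoch with exactly one behavioural state.

    States are ``wake``, ``sleep``, ``nap``, ``sedentary``, ``diary_removal``
    and ``no_diary``.  A diary night belongs to the day it starts, so the
    sleep interval of day *d* may spill onto day *d+1*.  Epochs on calendar
    days without any diary row stay ``no_diary`` regardless of spill-over,
    since such days are invalid downstream anyway.
    """
    states = np.full(series.n_epochs, STATE_WAKE, dtype="U16")

    diary_dates = {d.date for d in diary}
    day_idx = np.arange(series.n_epochs) * series.epoch_length
    day_idx = (day_idx + _midnight_offset(series)) // SECONDS_PER_DAY
    first_day = datetime.combine(series.start.date(), time()).date()
    days = np.array([first_day + timedelta(days=int(k)) for k in np.unique(day_idx)])
    covered = {d: (d in diary_dates) for d in days}
    no_diary_mask = np.array([not covered[first_day + timedelta(days=int(k))] for k in day_idx])

    def paint(start: datetime, end: datetime, label: str) -> None:
        states[_interval_slice(series, start, end)] = label

    # precedence, lowest first: sedentary < sleep < nap < diary_removal
    for d in diary:
        for a, b in d.sedentary:
            paint(a, b, STATE_SEDENTARY)
    for d in diary:
        paint(d.sleep_onset, d.sleep_offset, STATE_SLEEP)
    for d in diary:
        for a, b in d.naps:
            paint(a, b, STATE_NAP)
    for d in diary:
        for a, b in d.removals:
            paint(a, b, STATE_DIARY_REMOVAL)

    states[no_diary_mask] = STATE_NO_DIARY
    return states


def _midnight_offset(series: EpochSeries) -> int:
    """Seconds from the preceding midnight to the series start."""
    midnight = datetime.combine(series.start.date(), time())
    return int((series.start - midnight).total_seconds())
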