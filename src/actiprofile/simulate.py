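"""Ground-truthed synthetic actigraphy cohorts.

The generator emulates the data structure the pipeline consumes: multi-day
30-second activity-count series with circadian structure, caregiver sleep
diaries (nights, naps, device removals, evening sedentary periods), subject
metadata with a questionnaire overactivity score, and a truth manifest
recording everything that was injected.

The generative law is deliberately misaligned with the 9-function Fourier
analysis basis: the wake-epoch mean is a truncated single-harmonic cosine,

    lambda(t) = max(0, mesor + amplitude * cos(2*pi*(t - acrophase) / 24)),

multiplied by a square-wave overactivity factor inside the group's
overactivity windows.  Counts are overdispersed (gamma-mixed Poisson), sleep
epochs are zero-inflated with occasional small movement bursts, and night
awakenings insert wake-level activity into sleep.  Subjects carry trait-level
heterogeneity (mesor, amplitude, acrophase, sleep schedule, night-movement
propensity), mirroring the large between-child spread real cohorts show.
Device-removal artifacts force counts to zero and, unless the day's diary
entries are omitted, leave a matching diary record.

All event times are snapped to whole minutes (diary resolution), so diary
entries and injected truth agree exactly on the epoch grid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DiaryDay,
    EpochSeries,
    SubjectMeta,
    ValidationError,
    write_diary_csv,
    write_epoch_csv,
)

__all__ = [
    "GroupSpec",
    "ArtifactSpec",
    "SubjectTruth",
    "SimulatedSubject",
    "Cohort",
    "simulate_subject",
    "simulate_cohort",
    "preset_scenarios",
    "PRESET_NAMES",
]

EPOCH_LENGTH = 30
EPOCHS_PER_DAY = 86_400 // EPOCH_LENGTH
EPOCHS_PER_MINUTE = 60 // EPOCH_LENGTH
DEFAULT_START = date(2024, 3, 4)  # a Monday: 7 days span 5 weekdays + 2 weekend days


@dataclass
class GroupSpec:
    """Generative parameters of one cohort group.

    Activity is in Actiwatch-style counts per 30-s epoch; clock parameters are
    decimal hours.  The ``subject_*`` and night-trait fields describe
    between-child heterogeneity around the group means.
    """

    label: str
    n_subjects: int = 10
    # circadian mean structure (counts/epoch, clock hours)
    mesor: float = 250.0
    amplitude: float = 175.0
    acrophase: float = 13.5
    # sleep schedule (clock hours; sd = between-subject trait sd); defaults
    # follow the early schedules typical of syndromic cohorts (group mean
    # rise times around 05:00-06:55, bedtimes around 20:00-20:30)
    sleep_onset_mean: float = 20.25
    sleep_onset_sd: float = 0.5
    sleep_offset_mean: float = 6.25
    sleep_offset_sd: float = 0.6
    nightly_schedule_jitter: float = 0.25
    # night structure: prolonged, late-night-skewed awakenings with strong
    # between-child traits, reflecting the severe sleep disruption these
    # syndromic cohorts are recruited for
    night_awakening_rate: float = 2.5          # events / night (subject mean)
    awakening_duration_mean: float = 35.0      # minutes, exponential
    awakening_activity_fraction: float = 0.9   # of wake lambda during awakenings
    sleep_move_prob: float = 0.08              # per-epoch movement in sleep
    sleep_move_prob_sd: float = 0.03
    sleep_burst_mean: float = 35.0             # counts of a sleep movement burst
    # naps
    nap_probability: float = 0.0               # per day
    nap_window: tuple[float, float] = (12.0, 15.0)
    # overactivity
    overactivity_windows: list[tuple[float, float]] = field(default_factory=list)
    overactivity_multiplier: float = 1.0
    overactivity_link: float = 20.0            # questionnaire points per unit multiplier
    taq_base: float = 10.0
    taq_noise_sd: float = 2.5
    # count noise
    dispersion: float = 3.0                    # gamma shape of the gamma-Poisson mixture
    # between-subject trait heterogeneity within a (behaviourally homogeneous)
    # group; age and mobility effects, which widen real cohorts further, are
    # deliberately not modelled
    subject_mesor_sd: float = 25.0
    subject_amplitude_sd: float = 20.0
    subject_acrophase_sd: float = 0.35
    night_trait_sigma: float = 0.8             # lognormal sd of awakening-rate trait
    # daytime sedentary periods (diary-recorded, damped but non-zero activity)
    sedentary_probability: float = 0.5
    sedentary_window: tuple[float, float] = (17.5, 19.5)
    sedentary_damping: float = 0.1

    def __post_init__(self) -> None:
        if not (self.mesor >= self.amplitude >= 0):
            raise ValidationError("require mesor >= amplitude >= 0")
        for p in (self.nap_probability, self.sedentary_probability,
                  self.sleep_move_prob):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.night_awakening_rate < 0 or self.dispersion <= 0:
            raise ValidationError("rates must be >= 0 and dispersion > 0")
        lo, hi = self.nap_window
        if not (self.sleep_offset_mean <= lo < hi <= self.sleep_onset_mean):
            raise ValidationError("nap_window must lie inside the waking day")
        for a, b in self.overactivity_windows:
            if not 0 <= a < b <= 24:
                raise ValidationError("overactivity windows must be ordered clock intervals")


@dataclass
class ArtifactSpec:
    """Rates of injected device-removal artifacts and diary omissions."""

    wake_removal_rate: float = 0.5             # events / day
    wake_removal_duration_median: float = 25.0  # minutes (lognormal)
    wake_removal_duration_sigma: float = 0.5
    sleep_removal_probability: float = 0.05    # per night
    long_removal_probability: float = 0.02     # per day, >= 3 h events
    diary_omission_probability: float = 0.10   # per day: removal entries left out

    def __post_init__(self) -> None:
        for p in (self.sleep_removal_probability, self.long_removal_probability,
                  self.diary_omission_probability):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(wake_removal_rate=0.0, sleep_removal_probability=0.0,
                   long_removal_probability=0.0, diary_omission_probability=0.0)


@dataclass
class SubjectTruth:
    """Everything injected for one subject, on the epoch grid."""

    subject_id: str
    group: str
    n_epochs: int
    multiplier: float
    overactivity_windows: list[tuple[float, float]]
    taq_score: int
    removal_events: list[dict]           # start/end epoch, source, diary_logged
    sleep_intervals: list[tuple[int, int]]
    nap_intervals: list[tuple[int, int]]
    awakening_intervals: list[tuple[int, int]]
    traits: dict

    def removal_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_epochs, dtype=bool)
        for ev in self.removal_events:
            mask[ev["start"]:ev["end"]] = True
        return mask


@dataclass
class SimulatedSubject:
    series: EpochSeries
    diary: list[DiaryDay]
    meta: SubjectMeta
    truth: SubjectTruth


@dataclass
class Cohort:
    subjects: list[SimulatedSubject]
    days: int
    seed: int
    start_date: date

    def truth_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "days": self.days,
            "start_date": self.start_date.isoformat(),
            "subjects": {s.truth.subject_id: asdict(s.truth) for s in self.subjects},
        }

    def manifest_digest(self) -> str:
        payload = json.dumps(self.truth_manifest(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# helpers


def _snap_minute(hours: float) -> float:
    """Snap a decimal-hour instant to the diary's whole-minute resolution."""
    return round(hours * 60) / 60


def _hours_to_epoch(hours: float) -> int:
    return int(round(hours * 3600 / EPOCH_LENGTH))


def _clock_dt(day0: date, abs_hours: float) -> datetime:
    return datetime.combine(day0, time()) + timedelta(hours=abs_hours)


def _nb_counts(rng: np.random.Generator, lam: np.ndarray, shape: float) -> np.ndarray:
    """Gamma-mixed Poisson draws with mean ``lam`` and gamma shape ``shape``."""
    lam = np.asarray(lam, dtype=float)
    out = np.zeros(lam.shape)
    pos = lam > 0
    if pos.any():
        out[pos] = rng.poisson(rng.gamma(shape, lam[pos] / shape))
    return out


# ---------------------------------------------------------------------------
# subject simulation


def simulate_subject(
    group: GroupSpec,
    artifacts: ArtifactSpec | None = None,
    days: int = 7,
    seed: int = 0,
    subject_id: str | None = None,
    start_date: date = DEFAULT_START,
) -> SimulatedSubject:
    """Simulate one subject: epoch series, diary, metadata and truth entry.

    The recording spans ``days`` whole calendar days from midnight of
    ``start_date``.  The diary carries ``days + 1`` rows: one for the night
    preceding the first recorded day (so the first morning's sleep is
    diary-covered) and one per recorded day.  Fully deterministic per seed.
    """
    if days < 1:
        raise ValidationError("days must be >= 1")
    artifacts = artifacts or ArtifactSpec()
    rng = np.random.default_rng(seed)
    sid = subject_id or f"{group.label}-{seed}"
    n = days * EPOCHS_PER_DAY

    # --- subject traits -----------------------------------------------------
    mesor_i = max(20.0, rng.normal(group.mesor, group.subject_mesor_sd))
    amp_i = float(np.clip(rng.normal(group.amplitude, group.subject_amplitude_sd),
                          0.0, mesor_i))
    acro_i = rng.normal(group.acrophase, group.subject_acrophase_sd)
    onset_i = rng.normal(group.sleep_onset_mean, group.sleep_onset_sd)
    offset_i = rng.normal(group.sleep_offset_mean, group.sleep_offset_sd)
    onset_i = float(np.clip(onset_i, offset_i + 8.0, 23.8))
    # floor keeps natural sleep free of 2-h contiguous zero runs, the premise
    # of the 120-min non-wear rule on real wrist data
    p_move_i = float(np.clip(rng.normal(group.sleep_move_prob, group.sleep_move_prob_sd),
                             0.03, 0.3))
    awak_rate_i = group.night_awakening_rate * rng.lognormal(0.0, group.night_trait_sigma)
    multiplier = group.overactivity_multiplier
    taq = int(np.clip(round(group.taq_base + group.overactivity_link * (multiplier - 1)
                            + rng.normal(0, group.taq_noise_sd)), 0, 40))

    # --- nights -------------------------------------------------------------
    nights = []  # absolute decimal hours from start_date midnight
    for j in range(-1, days):
        onset = _snap_minute(j * 24 + onset_i + rng.normal(0, group.nightly_schedule_jitter))
        offset = _snap_minute((j + 1) * 24 + offset_i + rng.normal(0, group.nightly_schedule_jitter))
        nights.append((onset, offset))

    sleep_mask = np.zeros(n, dtype=bool)
    sleep_intervals = []
    for onset, offset in nights:
        i0 = max(_hours_to_epoch(onset), 0)
        i1 = min(_hours_to_epoch(offset), n)
        if i1 > i0:
            sleep_mask[i0:i1] = True
            sleep_intervals.append((i0, i1))

    # --- naps ---------------------------------------------------------------
    nap_mask = np.zeros(n, dtype=bool)
    nap_intervals: list[tuple[int, int]] = []
    naps_by_day: dict[int, list[tuple[float, float]]] = {}
    for j in range(days):
        if rng.random() < group.nap_probability:
            lo, hi = group.nap_window
            start = _snap_minute(j * 24 + rng.uniform(lo, max(lo, hi - 0.5)))
            dur_min = float(np.clip(round(rng.lognormal(np.log(45.0), 0.3)), 15, 100))
            end = _snap_minute(start + dur_min / 60)
            i0, i1 = _hours_to_epoch(start), min(_hours_to_epoch(end), n)
            if i1 > i0:
                nap_mask[i0:i1] = True
                nap_intervals.append((i0, i1))
                naps_by_day.setdefault(j, []).append((start, end))

    # --- night awakenings ---------------------------------------------------
    awake_mask = np.zeros(n, dtype=bool)
    awakening_intervals: list[tuple[int, int]] = []
    for onset, offset in nights:
        for _ in range(rng.poisson(awak_rate_i)):
            dur_min = float(np.clip(round(rng.exponential(group.awakening_duration_mean)), 1, 120))
            latest = offset - dur_min / 60
            if latest <= onset:
                continue
            # skew awakenings toward the later night (sleep lightens with
            # accumulated sleep pressure relief)
            start = _snap_minute(onset + (latest - onset) * rng.beta(2.0, 1.0))
            i0 = max(_hours_to_epoch(start), 0)
            i1 = min(_hours_to_epoch(start + dur_min / 60), n)
            if i1 > i0:
                awake_mask[i0:i1] = True
                awakening_intervals.append((i0, i1))

    # --- sedentary periods --------------------------------------------------
    sedentary_mask = np.zeros(n, dtype=bool)
    sedentary_by_day: dict[int, list[tuple[float, float]]] = {}
    for j in range(days):
        if rng.random() < group.sedentary_probability:
            lo, hi = group.sedentary_window
            start = _snap_minute(j * 24 + rng.uniform(lo, hi))
            dur_min = round(rng.uniform(30, 60))
            end = min(_snap_minute(start + dur_min / 60), nights[j + 1][0])
            i0, i1 = _hours_to_epoch(start), min(_hours_to_epoch(end), n)
            if i1 > i0:
                sedentary_mask[i0:i1] = True
                sedentary_by_day.setdefault(j, []).append((start, end))

    # --- counts -------------------------------------------------------------
    clock = (np.arange(n) / (3600 / EPOCH_LENGTH)) % 24.0
    lam = np.clip(mesor_i + amp_i * np.cos(2 * np.pi * (clock - acro_i) / 24.0), 0.0, None)
    in_window = np.zeros(n, dtype=bool)
    for a, b in group.overactivity_windows:
        in_window |= (clock >= a) & (clock < b)
    lam = np.where(in_window, lam * multiplier, lam)
    lam = np.where(sedentary_mask & ~sleep_mask & ~nap_mask,
                   lam * group.sedentary_damping, lam)

    asleep = (sleep_mask | nap_mask) & ~awake_mask
    counts = np.zeros(n)
    wakeish = ~asleep
    lam_eff = lam.copy()
    lam_eff[awake_mask & sleep_mask] *= group.awakening_activity_fraction
    counts[wakeish] = _nb_counts(rng, lam_eff[wakeish], group.dispersion)
    moving = rng.random(int(asleep.sum())) < p_move_i
    bursts = _nb_counts(rng, np.full(int(moving.sum()), group.sleep_burst_mean), 1.0)
    sleep_counts = np.zeros(int(asleep.sum()))
    sleep_counts[moving] = np.round(bursts)
    counts[asleep] = sleep_counts
    counts = np.round(counts)

    # --- artifacts ----------------------------------------------------------
    removal_events: list[dict] = []
    removals_by_day: dict[int, list[tuple[float, float]]] = {}
    omitted_days = {j for j in range(days)
                    if rng.random() < artifacts.diary_omission_probability}

    def add_removal(start_h: float, dur_min: float, source: str) -> None:
        start_h = _snap_minute(max(start_h, 0.0))
        end_h = _snap_minute(min(start_h + dur_min / 60, days * 24.0))
        i0, i1 = _hours_to_epoch(start_h), _hours_to_epoch(end_h)
        if i1 <= i0:
            return
        day = int(start_h // 24)
        # events starting past the last diary day cannot be logged
        logged = day < days and day not in omitted_days
        removal_events.append({"start": i0, "end": i1, "source": source,
                               "diary_logged": logged})
        counts[i0:i1] = 0
        if logged:
            removals_by_day.setdefault(day, []).append((start_h, end_h))

    for j in range(days):
        day_rise = nights[j][1] - j * 24      # this morning's offset, clock hours
        day_bed = nights[j + 1][0] - j * 24   # this evening's onset
        for _ in range(rng.poisson(artifacts.wake_removal_rate)):
            dur = float(np.clip(round(rng.lognormal(
                np.log(artifacts.wake_removal_duration_median),
                artifacts.wake_removal_duration_sigma)), 3, 120))
            lo, hi = day_rise + 0.5, day_bed - 0.5 - dur / 60
            if hi <= lo:
                continue
            add_removal(j * 24 + rng.uniform(lo, hi), dur, "wake_removal")
        if rng.random() < artifacts.long_removal_probability:
            dur = round(rng.uniform(185, 360))
            lo, hi = day_rise + 0.5, day_bed - dur / 60
            if hi > lo:
                add_removal(j * 24 + rng.uniform(lo, hi), dur, "long_removal")
    for onset, offset in nights:
        if rng.random() < artifacts.sleep_removal_probability:
            dur = round(rng.uniform(130, 200))
            if offset - dur / 60 > onset:
                add_removal(rng.uniform(onset, offset - dur / 60), dur, "sleep_removal")

    # --- diary --------------------------------------------------------------
    diary: list[DiaryDay] = []
    for j in range(-1, days):
        onset, offset = nights[j + 1]
        day_date = start_date + timedelta(days=j)
        rows_naps = naps_by_day.get(j, [])
        rows_rem = _merge_hour_intervals(removals_by_day.get(j, []))
        rows_sed = sedentary_by_day.get(j, [])
        am, pm = _ratings(rng, group, multiplier)
        diary.append(DiaryDay(
            date=day_date,
            sleep_onset=_clock_dt(start_date, onset),
            sleep_offset=_clock_dt(start_date, offset),
            naps=[(_clock_dt(start_date, a), _clock_dt(start_date, b)) for a, b in rows_naps],
            removals=[(_clock_dt(start_date, a), _clock_dt(start_date, b)) for a, b in rows_rem],
            sedentary=[(_clock_dt(start_date, a), _clock_dt(start_date, b)) for a, b in rows_sed],
            am_overactivity=am,
            pm_overactivity=pm,
        ))

    series = EpochSeries(
        subject_id=sid,
        start=datetime.combine(start_date, time()),
        epoch_length=EPOCH_LENGTH,
        counts=counts,
        flags=None,
    )
    meta = SubjectMeta(
        subject_id=sid,
        group=group.label,
        age=float(round(rng.uniform(4, 15), 1)),
        sex=str(rng.choice(["male", "female"])),
        mobility=str(rng.choice(["walks_unaided", "not_unaided"], p=[0.9, 0.1])),
        taq_overactivity=taq,
        lockdown_flag=False,
    )
    truth = SubjectTruth(
        subject_id=sid,
        group=group.label,
        n_epochs=n,
        multiplier=multiplier,
        overactivity_windows=list(group.overactivity_windows),
        taq_score=taq,
        removal_events=removal_events,
        sleep_intervals=sleep_intervals,
        nap_intervals=nap_intervals,
        awakening_intervals=awakening_intervals,
        traits={"mesor": mesor_i, "amplitude": amp_i, "acrophase": acro_i,
                "sleep_onset": onset_i, "sleep_offset": offset_i,
                "p_move": p_move_i, "awakening_rate": awak_rate_i},
    )
    return SimulatedSubject(series=series, diary=diary, meta=meta, truth=truth)


def _merge_hour_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for a, b in ordered[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


def _ratings(rng: np.random.Generator, group: GroupSpec, multiplier: float) -> tuple[int, int]:
    """Ordinal 0-4 caregiver ratings loosely tracking windowed overactivity."""
    def windowed(lo: float, hi: float) -> bool:
        return any(a < hi and b > lo for a, b in group.overactivity_windows)

    base_am = 2.0 * (multiplier - 1) * windowed(6.0, 12.0)
    base_pm = 2.0 * (multiplier - 1) * windowed(16.0, 22.0)
    am = int(np.clip(round(1 + base_am + rng.normal(0, 0.7)), 0, 4))
    pm = int(np.clip(round(1 + base_pm + rng.normal(0, 0.7)), 0, 4))
    return am, pm


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    groups: list[GroupSpec],
    artifacts: ArtifactSpec | None = None,
    days: int = 7,
    seed: int = 0,
    out_dir: str | Path | None = None,
    start_date: date = DEFAULT_START,
) -> Cohort:
    """Simulate all groups; optionally write the CSV inputs plus truth manifest.

    Subject seeds derive reproducibly from the cohort seed.  When ``out_dir``
    is given the function writes one ``epochs_<id>.csv`` per subject, a
    combined ``diary.csv``, ``metadata.csv`` and ``truth.json``.
    """
    artifacts = artifacts or ArtifactSpec()
    master = np.random.default_rng(seed)
    subjects: list[SimulatedSubject] = []
    for group in groups:
        for k in range(group.n_subjects):
            sub_seed = int(master.integers(0, 2**31 - 1))
            subjects.append(simulate_subject(
                group, artifacts, days=days, seed=sub_seed,
                subject_id=f"{group.label}{k:02d}", start_date=start_date,
            ))
    cohort = Cohort(subjects=subjects, days=days, seed=seed, start_date=start_date)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        diary_rows = []
        meta_rows = []
        for s in subjects:
            write_epoch_csv(s.series, out / f"epochs_{s.meta.subject_id}.csv")
            diary_rows.extend((s.meta.subject_id, d) for d in s.diary)
            meta_rows.append({
                "subject_id": s.meta.subject_id, "group": s.meta.group,
                "age": s.meta.age, "sex": s.meta.sex, "mobility": s.meta.mobility,
                "taq_overactivity": s.meta.taq_overactivity,
                "lockdown_flag": s.meta.lockdown_flag,
            })
        write_diary_csv(diary_rows, out / "diary.csv")
        pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(cohort.truth_manifest(), fh, indent=1, default=str)
    return cohort


# ---------------------------------------------------------------------------
# preset scenarios

PRESET_NAMES = ("null", "all_day_elevation", "early_morning_burst",
                "evening_burst", "phase_advanced")


def preset_scenarios(name: str) -> tuple[list[GroupSpec], ArtifactSpec]:
    """Fully parameterized two-group scenarios for pipeline exercise.

    ``null``: two identical groups.  The three burst scenarios elevate the
    high group's wake activity by 1.5x inside fixed clock windows (all-day,
    early-morning plus early-afternoon, or evening).  ``phase_advanced``
    shifts the second group's circadian peak and sleep schedule earlier
    without any overactivity window.
    """
    artifacts = ArtifactSpec()
    if name == "null":
        base = dict(n_subjects=8)
        return [GroupSpec(label="A", **base), GroupSpec(label="B", **base)], artifacts
    if name == "all_day_elevation":
        windows = [(5 + 20 / 60, 19.5)]
    elif name == "early_morning_burst":
        windows = [(6.75, 10.0), (13.0, 15.5)]
    elif name == "evening_burst":
        windows = [(17.5, 19.5)]
    elif name == "phase_advanced":
        low = GroupSpec(label="typical", n_subjects=10)
        high = GroupSpec(label="advanced", n_subjects=10, acrophase=11.5,
                         sleep_onset_mean=19.0, sleep_offset_mean=5.5)
        return [low, high], artifacts
    else:
        raise ValidationError(f"unknown scenario {name!r}; choose from {PRESET_NAMES}")
    low = GroupSpec(label="low", n_subjects=10)
    high = GroupSpec(label="high", n_subjects=10,
                     overactivity_windows=windows, overactivity_multiplier=1.5)
    return [low, high], artifacts
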