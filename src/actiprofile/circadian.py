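"""Averaged 24-hour activity profiles and the non-parametric M10 variables.

M10 is the mean activity count per epoch over the most active 10-hour window
of a subject's averaged 24-hour profile; M10 onset is the clock time that
window starts.  Windows step at the full grid resolution (30 s or 60 s), so
onset is resolved to the grid, and by default they may wrap across midnight.
Ties go to the earliest onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import SECONDS_PER_DAY, EpochSeries, ValidationError

__all__ = ["AverageDayProfile", "NPCRMetrics", "average_day_profile", "compute_m10"]

M10_WINDOW_SECONDS = 10 * 3600


@dataclass
class AverageDayProfile:
    """Per-clock-time mean activity across a subject's valid days."""

    grid_resolution: int  # seconds, 30 or 60
    values: np.ndarray    # length 86400 / grid_resolution
    n_days: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = SECONDS_PER_DAY // self.grid_resolution
        if SECONDS_PER_DAY % self.grid_resolution or self.values.size != expected:
            raise ValidationError(
                f"profile must have {expected} slots at {self.grid_resolution}-s resolution"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("profile values must be finite and non-negative")

    @property
    def n_slots(self) -> int:
        return int(self.values.size)


@dataclass
class NPCRMetrics:
    m10: float
    m10_onset: time
    grid_resolution: int
    wraparound: bool


def average_day_profile(cleaned: EpochSeries, resolution: int = 30) -> AverageDayProfile:
    """Collate the per-clock-time mean across whole valid days.

    ``cleaned`` must contain only valid, fully covered days (the cleaning
    stage's output).  At 60-s resolution the two 30-s epochs of each minute
    are averaged within-day first, which equals the overall mean per minute.
    """
    epd = cleaned.epochs_per_day
    if cleaned.n_epochs == 0 or cleaned.n_epochs % epd:
        raise ValidationError("cleaned series must contain at least one whole day")
    n_days = cleaned.n_epochs // epd
    by_day = cleaned.counts.reshape(n_days, epd)
    per_epoch = by_day.mean(axis=0)
    if resolution == cleaned.epoch_length:
        values = per_epoch
    elif resolution % cleaned.epoch_length == 0:
        fold = resolution // cleaned.epoch_length
        values = per_epoch.reshape(-1, fold).mean(axis=1)
    else:
        raise ValidationError("resolution must be a multiple of the epoch length")
    return AverageDayProfile(grid_resolution=resolution, values=values, n_days=n_days)


def compute_m10(profile: AverageDayProfile, wraparound: bool = True) -> NPCRMetrics:
    """Most active 10-hour window: mean level (M10) and start time (M10 onset).

    Every window start on the grid is evaluated; with ``wraparound`` the
    window may span midnight.  The maximal window mean is M10 and its start
    time the onset; exact ties resolve to the earliest start.
    """
    window = M10_WINDOW_SECONDS // profile.grid_resolution
    values = profile.values
    if wraparound:
        extended = np.concatenate([values, values[: window - 1]])
        sums = sliding_window_view(extended, window).sum(axis=-1)
    else:
        sums = sliding_window_view(values, window).sum(axis=-1)
    means = sums / window
    best = int(np.argmax(means))  # first occurrence of the maximum
    onset_seconds = best * profile.grid_resolution
    onset = time(onset_seconds // 3600, (onset_seconds % 3600) // 60, onset_seconds % 60)
    return NPCRMetrics(
        m10=float(means[best]),
        m10_onset=onset,
        grid_resolution=profile.grid_resolution,
        wraparound=wraparound,
    )
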