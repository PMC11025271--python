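"""Functional linear modelling of 24-hour activity with permutation F-tests.

Each subject's averaged day profile is projected onto a 9-function Fourier
basis (constant plus four sine/cosine harmonics at 24-hour periodicity),
giving one smooth periodic curve per subject.  Two groups' mean curves are
compared minute by minute with a one-way ANOVA F statistic on the evaluated
curves, and significance is assessed non-parametrically by permuting group
labels: the family-wise (maximum) critical value is the empirical
(1 - alpha) quantile of each permutation's maximum-over-time F, and the
pointwise critical value is the per-minute quantile curve.  Significant
intervals are the maximal runs where the observed F exceeds the maximum
critical value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circadian import AverageDayProfile
from .io import ValidationError

__all__ = [
    "FourierBasisConfig",
    "SubjectCurve",
    "PermutationConfig",
    "PermutationFResult",
    "SleepWindow",
    "fourier_design",
    "fit_fourier",
    "evaluate_curve",
    "pointwise_f",
    "permutation_f_test",
    "annotate_sleep_overlap",
    "temporal_jaccard",
]

PERIOD_HOURS = 24.0


@dataclass
class FourierBasisConfig:
    n_basis: int = 9          # constant + (n_basis-1)/2 sin/cos harmonic pairs
    period: float = PERIOD_HOURS
    eval_grid: int = 1440     # evaluation points per day (minutes)

    def __post_init__(self) -> None:
        if self.n_basis < 1 or self.n_basis % 2 == 0:
            raise ValidationError("n_basis must be odd and >= 1")
        if self.period != PERIOD_HOURS:
            raise ValidationError("the activity model is fixed at a 24-hour period")

    @property
    def n_harmonics(self) -> int:
        return (self.n_basis - 1) // 2


@dataclass
class SubjectCurve:
    """Fourier coefficients (c0, a1, b1, ...) for basis {1, sin(2*pi*k*t/24), cos(...)}."""

    coefficients: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or not np.all(np.isfinite(self.coefficients)):
            raise ValidationError("coefficients must be a finite 1-d vector")

    @property
    def n_basis(self) -> int:
        return int(self.coefficients.size)


@dataclass
class PermutationConfig:
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    method: str = "auto"  # auto | monte_carlo | exact

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.method not in {"auto", "monte_carlo", "exact"}:
            raise ValidationError(f"unknown permutation method {self.method!r}")


@dataclass
class PermutationFResult:
    grid_minutes: np.ndarray          # evaluation grid, minutes past midnight
    f_observed: np.ndarray
    max_critical: float
    pointwise_critical: np.ndarray
    significant_intervals: list[tuple[float, float]]  # minutes, half-open
    p_global: float
    alpha: float
    method: str                       # monte_carlo | exact
    n_permutations: int


@dataclass
class SleepWindow:
    """Group-level mean sleep timings, as decimal clock hours in [0, 24)."""

    group: str
    mean_sleep_offset: float  # morning rise
    mean_sleep_onset: float   # evening sleep

    def __post_init__(self) -> None:
        for v in (self.mean_sleep_offset, self.mean_sleep_onset):
            if not 0 <= v < 24:
                raise ValidationError("sleep timings must lie in [0, 24) hours")


# ---------------------------------------------------------------------------
# basis fitting


def fourier_design(t_hours: np.ndarray, n_basis: int) -> np.ndarray:
    """Design matrix [1, sin(2*pi*k*t/24), cos(2*pi*k*t/24)] for k = 1..(n_basis-1)/2."""
    t_hours = np.asarray(t_hours, dtype=float)
    cols = [np.ones_like(t_hours)]
    for k in range(1, (n_basis - 1) // 2 + 1):
        w = 2 * np.pi * k * t_hours / PERIOD_HOURS
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


def fit_fourier(profile: AverageDayProfile, config: FourierBasisConfig | None = None,
                subject_id: str | None = None) -> SubjectCurve:
    """Least-squares projection of a day profile onto the Fourier basis.

    Profile slot ``s`` is associated with its left edge ``s * resolution``;
    on a full uniform day grid the basis columns are orthogonal and the
    normal equations are satisfied to machine precision.
    """
    config = config or FourierBasisConfig()
    t = np.arange(profile.n_slots) * profile.grid_resolution / 3600.0
    design = fourier_design(t, config.n_basis)
    coef, *_ = np.linalg.lstsq(design, profile.values, rcond=None)
    return SubjectCurve(coefficients=coef, subject_id=subject_id)


def evaluate_curve(curve: SubjectCurve, grid: int | np.ndarray = 1440) -> np.ndarray:
    """Evaluate the Fourier sum on a minute grid (or at given times in minutes)."""
    if np.isscalar(grid):
        minutes = np.arange(int(grid)) * (24 * 60 / int(grid))
    else:
        minutes = np.asarray(grid, dtype=float)
    design = fourier_design(minutes / 60.0, curve.n_basis)
    return design @ curve.coefficients


def _grid_minutes(grid: int | np.ndarray) -> np.ndarray:
    if np.isscalar(grid):
        return np.arange(int(grid)) * (24 * 60 / int(grid))
    return np.asarray(grid, dtype=float)


def _curve_matrix(curves: Sequence[SubjectCurve], grid: int | np.ndarray) -> np.ndarray:
    return np.vstack([evaluate_curve(c, grid) for c in curves])


# ---------------------------------------------------------------------------
# F statistics


def _f_two_groups(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per column for a single 0/1 split (rows = subjects)."""
    return _f_many(data, is_a[None, :])[0]


def _f_many(data: np.ndarray, splits: np.ndarray) -> np.ndarray:
    """Vectorised two-group F curves for many label assignments.

    ``data`` is (n_subjects, n_times); ``splits`` is (n_splits, n_subjects)
    boolean with a fixed number of True (group A) per row.  Returns
    (n_splits, n_times).  Degenerate columns with zero within-group variance
    get F = +inf where the group means differ and 0 otherwise.
    """
    n, _ = data.shape
    n_a = int(splits[0].sum())
    n_b = n - n_a
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least 2 subjects")
    grand = data.mean(axis=0)
    sst = ((data - grand) ** 2).sum(axis=0)
    sum_a = splits.astype(float) @ data          # (n_splits, n_times)
    mean_a = sum_a / n_a
    mean_b = (data.sum(axis=0) - sum_a) / n_b
    ssb = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    ssw = np.maximum(sst - ssb, 0.0)
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / msw
    f = np.where(msw == 0, np.where(ssb > 0, np.inf, 0.0), f)
    return f


def pointwise_f(
    curves_a: Sequence[SubjectCurve],
    curves_b: Sequence[SubjectCurve],
    grid: int | np.ndarray = 1440,
) -> np.ndarray:
    """Observed F(t): between-group over within-group mean square at each time."""
    data = np.vstack([_curve_matrix(curves_a, grid), _curve_matrix(curves_b, grid)])
    is_a = np.zeros(data.shape[0], dtype=bool)
    is_a[: len(curves_a)] = True
    return _f_two_groups(data, is_a)


def _significant_intervals(
    f_obs: np.ndarray, critical: float, minutes: np.ndarray
) -> list[tuple[float, float]]:
    exceeds = f_obs > critical
    step = float(minutes[1] - minutes[0]) if minutes.size > 1 else 1.0
    out = []
    padded = np.concatenate(([False], exceeds, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        out.append((float(minutes[i0]), float(minutes[i1 - 1]) + step))
    return out


def permutation_f_test(
    curves: Sequence[SubjectCurve],
    labels: Sequence[str],
    grid: int | np.ndarray = 1440,
    perm_config: PermutationConfig | None = None,
) -> PermutationFResult:
    """Two-group permutation F-test with maximum and pointwise critical values.

    Group sizes are preserved under relabelling.  Monte-Carlo sampling is used
    by default; when the number of distinct relabelings does not exceed the
    requested permutation count (or ``method='exact'``) the full enumeration
    is used instead.  The Monte-Carlo global p follows the add-one convention
    ``(1 + #{max F_perm >= max F_obs}) / (P + 1)``, which is valid under
    exchangeability; critical values are lower-interpolation empirical
    quantiles.  Results are reproducible per seed and invariant to the order
    subjects are supplied in.
    """
    cfg = perm_config or PermutationConfig()
    labels = list(labels)
    if len(labels) != len(curves):
        raise ValidationError("labels and curves must have equal length")
    uniques = sorted(set(labels))
    if len(uniques) != 2:
        raise ValidationError(f"exactly two groups required, got {uniques}")

    # canonical subject order: by label, then coefficients — makes the test
    # invariant to input ordering
    order = sorted(
        range(len(curves)),
        key=lambda i: (labels[i], tuple(curves[i].coefficients)),
    )
    curves = [curves[i] for i in order]
    labels = [labels[i] for i in order]

    minutes = _grid_minutes(grid)
    data = _curve_matrix(curves, minutes)
    is_a = np.array([lab == uniques[0] for lab in labels])
    n, n_a = data.shape[0], int(is_a.sum())
    if n_a < 2 or n - n_a < 2:
        raise ValidationError("each group needs at least 2 subjects")

    f_obs = _f_two_groups(data, is_a)
    max_obs = float(np.max(f_obs))
    # analytically tied relabelings (e.g. a split and its complement) must
    # count as >= despite float-level asymmetry
    tie_tol = 1e-9 * max_obs if np.isfinite(max_obs) else 0.0

    n_distinct = math.comb(n, n_a)
    exact = cfg.method == "exact" or (cfg.method == "auto" and n_distinct <= cfg.n_permutations)
    if exact:
        splits = np.zeros((n_distinct, n), dtype=bool)
        for row, combo in enumerate(itertools.combinations(range(n), n_a)):
            splits[row, list(combo)] = True
        f_perm = _f_many(data, splits)
        max_perm = f_perm.max(axis=1)
        p_global = float(np.mean(max_perm >= max_obs - tie_tol))  # identity included
        method = "exact"
        n_used = n_distinct
    else:
        rng = np.random.default_rng(cfg.seed)
        splits = np.zeros((cfg.n_permutations, n), dtype=bool)
        for row in range(cfg.n_permutations):
            splits[row, rng.choice(n, size=n_a, replace=False)] = True
        f_perm = _f_many(data, splits)
        max_perm = f_perm.max(axis=1)
        p_global = float((1 + np.sum(max_perm >= max_obs - tie_tol))
                         / (cfg.n_permutations + 1))
        method = "monte_carlo"
        n_used = cfg.n_permutations

    # +inf entries (degenerate zero-variance splits) sort above everything,
    # which is exactly the conservative behaviour the quantile needs
    max_critical = float(np.quantile(max_perm, 1 - cfg.alpha, method="lower"))
    pointwise_critical = np.quantile(f_perm, 1 - cfg.alpha, axis=0, method="lower")

    return PermutationFResult(
        grid_minutes=minutes,
        f_observed=f_obs,
        max_critical=max_critical,
        pointwise_critical=pointwise_critical,
        significant_intervals=_significant_intervals(f_obs, max_critical, minutes),
        p_global=p_global,
        alpha=cfg.alpha,
        method=method,
        n_permutations=n_used,
    )


# ---------------------------------------------------------------------------
# interpretation helpers


def annotate_sleep_overlap(
    result: PermutationFResult,
    windows: tuple[SleepWindow, SleepWindow],
) -> list[dict]:
    """Classify each significant interval against the groups' mean sleep times.

    An interval is ``wake_only`` when it lies inside [latest mean sleep
    offset, earliest mean sleep onset] of the two groups — the span in which
    both groups are, on average, awake — otherwise ``overlaps_sleep`` with
    the crossed boundary named.
    """
    w1, w2 = windows
    wake_lo = max(w1.mean_sleep_offset, w2.mean_sleep_offset) * 60.0
    wake_hi = min(w1.mean_sleep_onset, w2.mean_sleep_onset) * 60.0
    out = []
    for start, end in result.significant_intervals:
        boundaries = []
        if start < wake_lo:
            late_riser = max((w1, w2), key=lambda w: w.mean_sleep_offset)
            boundaries.append(f"precedes_offset:{late_riser.group}")
        if end > wake_hi:
            early_sleeper = min((w1, w2), key=lambda w: w.mean_sleep_onset)
            boundaries.append(f"exceeds_onset:{early_sleeper.group}")
        out.append({
            "interval": (start, end),
            "label": "wake_only" if not boundaries else "overlaps_sleep",
            "boundaries": boundaries,
        })
    return out


def temporal_jaccard(
    intervals_a: Sequence[tuple[float, float]],
    intervals_b: Sequence[tuple[float, float]],
    resolution_minutes: float = 1.0,
) -> float:
    """Jaccard overlap of two unions of clock intervals (minutes past midnight)."""
    n = int(round(24 * 60 / resolution_minutes))
    grid = (np.arange(n) + 0.5) * resolution_minutes

    def mask(intervals: Sequence[tuple[float, float]]) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        for a, b in intervals:
            m |= (grid >= a) & (grid < b)
        return m

    ma, mb = mask(intervals_a), mask(intervals_b)
    union = np.sum(ma | mb)
    if union == 0:
        return 1.0
    return float(np.sum(ma & mb) / union)
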