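"""End-to-end orchestration: clean -> profile -> metrics -> group comparison.

Thin glue over the stage modules, used by the command-line interface, the
test-suite and the acceptance script.  Each helper takes and returns the
stage types directly so any step can be swapped or inspected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circadian import AverageDayProfile, NPCRMetrics, average_day_profile, compute_m10
from .cleaning import CleaningConfig, apply_protocol, include_subject
from .flm import (
    FourierBasisConfig,
    PermutationConfig,
    PermutationFResult,
    SubjectCurve,
    fit_fourier,
    permutation_f_test,
)
from .simulate import Cohort, SimulatedSubject

__all__ = [
    "SubjectResult",
    "process_subject",
    "process_cohort",
    "metrics_table",
    "compare_groups",
    "removal_detection_confusion",
]


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    included: bool
    n_valid_days: int
    diagnostics: dict
    profile: AverageDayProfile | None
    metrics: NPCRMetrics | None
    curve: SubjectCurve | None


def process_subject(
    subject: SimulatedSubject,
    cleaning: CleaningConfig | None = None,
    resolution: int = 30,
    basis: FourierBasisConfig | None = None,
) -> SubjectResult:
    """Clean one subject and derive profile, M10 metrics and Fourier curve."""
    cleaning = cleaning or CleaningConfig()
    cleaned, reports, _ = apply_protocol(subject.series, subject.diary, cleaning)
    included, diagnostics = include_subject(reports, cleaning)
    if cleaned.n_epochs == 0:
        return SubjectResult(subject.meta.subject_id, subject.meta.group, False,
                             0, diagnostics, None, None, None)
    profile = average_day_profile(cleaned, resolution)
    metrics = compute_m10(profile)
    curve = fit_fourier(profile, basis, subject_id=subject.meta.subject_id)
    return SubjectResult(
        subject_id=subject.meta.subject_id,
        group=subject.meta.group,
        included=included,
        n_valid_days=diagnostics["n_valid_days"],
        diagnostics=diagnostics,
        profile=profile,
        metrics=metrics,
        curve=curve,
    )


def process_cohort(
    cohort: Cohort,
    cleaning: CleaningConfig | None = None,
    resolution: int = 30,
    basis: FourierBasisConfig | None = None,
) -> list[SubjectResult]:
    return [process_subject(s, cleaning, resolution, basis) for s in cohort.subjects]


def metrics_table(results: list[SubjectResult]) -> pd.DataFrame:
    """Per-subject M10 table (included subjects only)."""
    rows = []
    for r in results:
        if not r.included or r.metrics is None:
            continue
        rows.append({
            "subject_id": r.subject_id,
            "group": r.group,
            "n_valid_days": r.n_valid_days,
            "m10": r.metrics.m10,
            "m10_onset": r.metrics.m10_onset.isoformat(),
            "m10_onset_minutes": r.metrics.m10_onset.hour * 60
            + r.metrics.m10_onset.minute
            + r.metrics.m10_onset.second / 60,
        })
    return pd.DataFrame(rows)


def compare_groups(
    results: list[SubjectResult],
    group_a: str,
    group_b: str,
    perm_config: PermutationConfig | None = None,
    grid: int = 1440,
) -> PermutationFResult:
    """Permutation F-test between two groups' included subjects."""
    curves, labels = [], []
    for r in results:
        if r.included and r.curve is not None and r.group in (group_a, group_b):
            curves.append(r.curve)
            labels.append(r.group)
    return permutation_f_test(curves, labels, grid=grid, perm_config=perm_config)


def removal_detection_confusion(
    cohort: Cohort,
    cleaning: CleaningConfig | None = None,
) -> dict:
    """Per-epoch removal detection vs the truth manifest, pooled over subjects.

    Sensitivity = detected removal epochs / injected removal epochs;
    specificity = undisturbed epochs / epochs with no injected removal.
    """
    from .cleaning import detect_removal_intervals
    from .io import align_to_epochs

    cleaning = cleaning or CleaningConfig()
    tp = fp = fn = tn = 0
    for s in cohort.subjects:
        states = align_to_epochs(s.diary, s.series)
        detected = detect_removal_intervals(s.series, states, cleaning)
        det_mask = np.zeros(s.series.n_epochs, dtype=bool)
        for r in detected:
            det_mask[r.start:r.end] = True
        truth_mask = s.truth.removal_mask()
        tp += int(np.sum(det_mask & truth_mask))
        fp += int(np.sum(det_mask & ~truth_mask))
        fn += int(np.sum(~det_mask & truth_mask))
        tn += int(np.sum(~det_mask & ~truth_mask))
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": sensitivity, "specificity": specificity}
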