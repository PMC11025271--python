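"""Scalar group statistics: median splits, correlations, rank tests and
Bonferroni families.

These are the conventional tests wrapped behind a uniform result type:
Pearson correlations between the circadian metrics and questionnaire
overactivity scores, Kruskal-Wallis omnibus tests with Dunn-Bonferroni
post-hocs for four-group M10 comparisons, Student t / Mann-Whitney U
two-sample comparisons, chi-square proportion tests, boxplot-fence outlier
screening for M10 onset, and the two Bonferroni test families (0.05/9 and
0.05/5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "StatResult",
    "SplitResult",
    "FamilyCorrection",
    "median_split",
    "correlate",
    "kruskal_wallis",
    "dunn_bonferroni",
    "two_sample_test",
    "chi_square_proportions",
    "bonferroni_threshold",
    "flag_onset_outliers",
]


@dataclass
class StatResult:
    statistic: str            # r | t | U | H | z | chi2
    value: float
    p_value: float
    df: float | tuple | None = None
    n: int | tuple | None = None
    sidedness: str = "two"    # one | two
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p_value must lie in [0, 1]")


@dataclass
class SplitResult:
    median: float
    high_ids: list
    low_ids: list
    tie_policy: str
    degenerate: bool  # high group empty (all scores at or below the median)


@dataclass
class FamilyCorrection:
    family: str
    m: int
    alpha_family: float = 0.05

    @property
    def threshold(self) -> float:
        return self.alpha_family / self.m

    @property
    def threshold_display(self) -> float:
        return round(self.threshold, 3)


def median_split(scores: Mapping[str, float], tie_policy: str = "low") -> SplitResult:
    """Dichotomize ids at the sample median of their scores.

    With the default low-inclusive policy, scores strictly above the median go
    high and the rest low, so the high group sits strictly above the median.
    """
    if not scores:
        raise ValidationError("median_split needs at least one score")
    if tie_policy not in {"low", "high"}:
        raise ValidationError("tie_policy must be 'low' or 'high'")
    values = np.array(list(scores.values()), dtype=float)
    med = float(np.median(values))
    if tie_policy == "low":
        high = [k for k, v in scores.items() if v > med]
        low = [k for k, v in scores.items() if v <= med]
    else:
        high = [k for k, v in scores.items() if v >= med]
        low = [k for k, v in scores.items() if v < med]
    return SplitResult(median=med, high_ids=high, low_ids=low,
                       tie_policy=tie_policy, degenerate=not high)


def _alternative(sidedness: str) -> str:
    mapping = {"two": "two-sided", "greater": "greater", "less": "less"}
    if sidedness not in mapping:
        raise ValidationError("sidedness must be 'two', 'greater' or 'less'")
    return mapping[sidedness]


def correlate(x: Sequence[float], y: Sequence[float], sidedness: str = "two") -> StatResult:
    """Pearson r with a t-distributed p value; missing pairs dropped listwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y, alternative=_alternative(sidedness))
    return StatResult(
        statistic="r", value=float(res.statistic), p_value=float(res.pvalue),
        df=x.size - 2, n=int(x.size), sidedness="two" if sidedness == "two" else "one",
        detail={"n_dropped": int(np.sum(~keep))},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H with tie correction, chi-square p on k-1 df."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(s.size < 1 for s in samples) or sum(s.size for s in samples) < 3:
        raise ValidationError("kruskal_wallis needs >=2 non-empty groups, total n >= 3")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return StatResult(statistic="H", value=0.0, p_value=1.0,
                          df=len(samples) - 1, n=tuple(s.size for s in samples))
    h, p = sps.kruskal(*samples)
    return StatResult(statistic="H", value=float(h), p_value=float(p),
                      df=len(samples) - 1, n=tuple(s.size for s in samples))


def dunn_bonferroni(groups: Sequence[Sequence[float]],
                    labels: Sequence[str] | None = None) -> list[StatResult]:
    """Dunn's pairwise z tests on pooled mean ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) over tied value groups; each two-sided p is
    multiplied by the number of pairs and capped at 1.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValidationError("dunn_bonferroni needs at least 2 groups")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(samples))]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [s.size for s in samples]
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(samples))]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance_core = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        variance_core -= tie_term / (12.0 * (n_total - 1))

    n_pairs = len(samples) * (len(samples) - 1) // 2
    results = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = np.sqrt(variance_core * (1 / sizes[i] + 1 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            raw = 2 * sps.norm.sf(abs(z))
            results.append(StatResult(
                statistic="z", value=float(z),
                p_value=float(min(1.0, raw * n_pairs)),
                n=(sizes[i], sizes[j]),
                detail={"pair": (labels[i], labels[j]), "p_raw": float(raw)},
            ))
    return results


def two_sample_test(a: Sequence[float], b: Sequence[float], kind: str = "student_t",
                    sidedness: str = "two") -> StatResult:
    """Independent two-sample comparison: Student t or Mann-Whitney U.

    The U test uses the normal approximation with tie correction and no
    continuity correction (the convention of the mainstream SPSS output the
    reported statistics follow).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    alt = _alternative(sidedness)
    side = "two" if sidedness == "two" else "one"
    if kind == "student_t":
        if a.size < 2 or b.size < 2:
            raise ValidationError("t test needs n >= 2 per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            raise ValidationError("t undefined with zero pooled variance")
        res = sps.ttest_ind(a, b, equal_var=True, alternative=alt)
        return StatResult(statistic="t", value=float(res.statistic),
                          p_value=float(res.pvalue), df=a.size + b.size - 2,
                          n=(a.size, b.size), sidedness=side)
    if kind == "mann_whitney":
        if a.size < 1 or b.size < 1:
            raise ValidationError("U test needs n >= 1 per group")
        res = sps.mannwhitneyu(a, b, alternative=alt, method="asymptotic",
                               use_continuity=False)
        return StatResult(statistic="U", value=float(res.statistic),
                          p_value=float(res.pvalue), n=(a.size, b.size), sidedness=side)
    raise ValidationError(f"unknown test kind {kind!r}")


def chi_square_proportions(table: Sequence[Sequence[float]]) -> StatResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValidationError("table must be 2-d with non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined with a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult(statistic="chi2", value=float(res.statistic),
                      p_value=float(res.pvalue),
                      df=(table.shape[0] - 1) * (table.shape[1] - 1),
                      n=int(table.sum()))


def bonferroni_threshold(alpha_family: float, m: int, family: str = "") -> FamilyCorrection:
    """Per-test threshold alpha/m for a family of m tests."""
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    if not 0 < alpha_family < 1:
        raise ValidationError("alpha_family must lie in (0, 1)")
    return FamilyCorrection(family=family, m=m, alpha_family=alpha_family)


def flag_onset_outliers(values: Mapping[str, float], method: str = "iqr",
                        k: float = 1.5, manual: Sequence[str] = ()) -> list[str]:
    """Flag M10-onset outliers on the minutes-since-midnight scale.

    Default rule: boxplot fences [Q1 - k*IQR, Q3 + k*IQR].  ``method='manual'``
    flags a caller-supplied id list (reproducing a by-hand exclusion), and
    ``method='none'`` disables flagging.
    """
    if method == "none":
        return []
    if method == "manual":
        return [i for i in values if i in set(manual)]
    if method != "iqr":
        raise ValidationError(f"unknown outlier method {method!r}")
    if len(values) < 4:
        raise ValidationError("iqr rule needs at least 4 values")
    arr = np.array(list(values.values()), dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
    return [i for i, v in values.items() if v < lo or v > hi]
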