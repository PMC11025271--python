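# Methods

This note documents the models and procedures `actiprofile` implements, the
parameters that matter, the synthetic-cohort design, and the numerical
conventions chosen where the underlying methodology leaves room.

## Data model

Activity is represented as non-negative integer counts accumulated per
30-second epoch by a wrist-worn uniaxial accelerometer (Actiwatch-style:
per-second maximum accelerations summed over the epoch).  The epoch grid is
half-open and left-aligned — the epoch stamped *t* covers [*t*, *t* + 30 s) —
and diary intervals map to epochs by any-overlap, the conservative choice
for artifact handling.  All times are local clock times; the analyses are
clock-time based, so recordings spanning daylight-saving transitions are not
supported (the reader rejects off-grid spacing rather than reinterpreting
it).  A calendar day runs 00:00–24:00 and a diary night belongs to the day
it starts.

## Cleaning protocol

Stages run in a fixed order: diary alignment → removal detection →
systematic-error screening → day classification → imputation → subject
inclusion.

* **Inactivity** means a count of exactly 0.  An un-worn device accumulates
  nothing, whereas worn sleep shows intermittent small movements.
* **Wake rule**: a maximal run of zero-count epochs, every epoch of which is
  wake-labelled (not sedentary, nap or sleep), lasting ≥ 10 min
  (`wake_inactivity_min`).  A diary sedentary interval splits such a run;
  each wake-only remainder must clear the threshold by itself.
* **Sleep rule**: a zero run lying entirely within sleep or naps lasting
  ≥ 120 min (`sleep_inactivity_min`).  Naps count as sleep here because
  diaries record them precisely and stillness during them is expected.
* **Systematic error**: any 24-h window containing no epoch at or below the
  rest threshold (default 0) flags every calendar day it touches —
  "constant activity, no rest" indicates a device fault.
* **Day validity**: a day is invalid with ≥ 3 h total removal
  (`day_exclusion_hours`), a missing diary row, a systematic-error flag, or
  partial recording coverage (first/last part-days; per-clock-time averaging
  requires whole days).
* **Imputation** replaces each removed epoch on a valid day with the mean
  count at the same clock time over the other valid days, using only donor
  epochs that are themselves neither removed nor missing.  A removed clock
  epoch with no donor raises an error naming the epoch, so the caller can
  invalidate the day instead.  Diary-recorded removals count toward the 3-h
  day total along with rule detections.
* **Subject inclusion** requires ≥ 5 valid days (`min_valid_days`).  The
  ≥ 4-weekday / ≥ 1-weekend-day composition is reported as a diagnostic
  only, mirroring its descriptive role in the protocol.

## Circadian metrics

The average day profile is the per-clock-time mean across valid days, at
30-s or 60-s resolution.  M10 evaluates every contiguous 10-hour window at
full grid resolution; by default windows may wrap across midnight (the
non-wrap mode is available, and both are tested against an exhaustive scan).
Ties resolve to the earliest onset.  M10 is reported in counts/epoch at the
profile's native resolution, recorded alongside to prevent cross-resolution
comparisons.

## Functional linear modelling and permutation F-tests

Each subject contributes one curve: the least-squares projection of their
average day profile onto the 9-function Fourier basis at fixed 24-h period
(constant plus four harmonic pairs).  On a uniform full-day grid the basis
is orthogonal, so the fit is exact for any ≤4-harmonic signal.  Group
comparison evaluates the curves on a minute grid and computes the one-way
ANOVA F at each minute; for two groups F(t) equals the squared two-sample
t statistic, an identity the tests verify.  At a grid point with zero
within-group variance, F is +∞ when group means differ and 0 otherwise.

The null distribution comes from relabelling subjects with group sizes
preserved.  Monte-Carlo sampling (default 5000 relabelings) switches to
exhaustive enumeration whenever the number of distinct relabelings does not
exceed the requested count.  The family-wise (maximum) critical value is the
empirical (1−α) quantile — lower-interpolation order statistic, conservative
and reproducible — of each permutation's max-over-time F; the pointwise
critical value applies the same quantile per minute and never exceeds the
maximum critical value.  The global p uses the add-one convention
(1 + #{max F_perm ≥ max F_obs})/(P + 1) under Monte-Carlo sampling, which is
valid under exchangeability, and the plain proportion (identity included)
under enumeration.  Analytically tied relabelings (a split and its
complement) are counted as ties despite float-level asymmetry (relative
tolerance 1e−9).  Results are reproducible per seed and invariant to subject
ordering, achieved by canonically ordering subjects before drawing
relabelings.  Significant intervals — maximal runs with observed F above the
maximum critical value — can be classified against the groups' mean sleep
offset/onset times as `wake_only` or `overlaps_sleep`.

α defaults follow the two test families of the analysis design: 0.006
(= 0.05/9) for high/low questionnaire-score comparisons and 0.01 (= 0.05/5)
for syndrome-versus-comparison-group contrasts; both are configurable.

## Scalar statistics

Median splits are low-inclusive (score ≤ median → low), keeping the high
group strictly above the reported medians; the degenerate all-tied case is
flagged.  Pearson correlations drop incomplete pairs listwise and report the
count.  Kruskal–Wallis uses the standard tie correction with a χ² reference
on k−1 df; Dunn post-hoc z statistics come from pooled mean ranks with the
t³−t tie term, and p values are Bonferroni-multiplied by the number of pairs
and capped at 1.  Mann–Whitney U uses the tie-corrected normal approximation
without continuity correction (the mainstream SPSS convention the reported
statistics follow); χ² is Pearson's without continuity correction.  Default
sidedness is two-sided with per-analysis overrides (several published
comparisons are only consistent with one-sided reporting).  M10-onset
outliers use 1.5·IQR boxplot fences on minutes-since-midnight by default; a
manual exclusion list reproduces by-hand removals exactly, and the rule can
be disabled.

## Synthetic cohort design

The generator produces the statistical structure the analyses assume while
staying deliberately misaligned with the analysis basis: the wake-epoch mean
is a truncated single-harmonic cosine

λ(t) = max(0, mesor + amplitude·cos(2π(t − acrophase)/24)),

multiplied by a square-wave factor inside the group's overactivity windows —
so FLM recovery tests are non-circular (a 9-function Fourier fit cannot
represent the truth exactly).  Counts are gamma-mixed Poisson
(overdispersed; shape 3 by default) because real activity counts are bursty.

Defaults, with rationale:

* **mesor 250, amplitude 175 counts/epoch, acrophase 13:30** — yields M10
  values in the high-300s/low-400s counts/epoch and M10 onsets in the
  08:00–09:30 range, the scale reported for school-age cohorts.
* **Sleep schedule: onset 20:15 ± 0.5 h, offset 06:15 ± 0.6 h between
  subjects, ± 15 min night-to-night** — the early schedules reported for
  syndromic groups (group mean rise times around 05:00–06:55, bedtimes
  around 20:00–20:30).
* **Night structure** — prolonged awakenings (2.5/night on average,
  exponential durations with 35-min mean, skewed toward the later night) at
  near-wake activity, plus per-epoch movement bursts in sleep (probability
  0.08, burst mean 35 counts).  Subject-level traits (lognormal awakening
  rate, σ = 0.8; movement probability floored at 0.03) reproduce the large
  between-child spread in night activity that severely sleep-disrupted
  cohorts show.  The movement-probability floor also encodes the premise of
  the 120-min non-wear rule: worn sleep essentially never yields two hours
  of contiguous zeros.
* **Between-subject circadian traits** (mesor SD 25, amplitude SD 20,
  acrophase SD 0.35 h) represent a behaviourally homogeneous group.  Real
  cohorts spanning ages 4–15 and mixed mobility show wider M10 spreads;
  demographic effects on activity are deliberately out of the simulator's
  scope, so passing recovery tests speak to cohorts after such covariates
  are controlled, not to raw heterogeneous samples.
* **Questionnaire link** — score = 10 + 20·(multiplier − 1) + N(0, 2.5),
  truncated to [0, 40], giving a monotone link between the injected daytime
  elevation and the score that median splits and correlations can target.
* **Artifacts** — wake removals 0.5/day (lognormal durations, median
  25 min), sleep removals on 5% of nights (130–200 min), ≥3-h removals on
  2% of days, and a 10% daily probability that the diary omits that day's
  removal entries (exercising the wake/sleep rules rather than the diary
  path).  Injected removals force counts to 0 and, unless omitted, write
  matching diary entries; all event times are snapped to whole minutes, the
  diary's resolution, so truth and diary agree on the epoch grid.
* The diary includes one extra row for the night before the first recorded
  day, so the first morning's sleep is diary-covered and day 1 is not
  spuriously flagged by the wake rule.

What the simulator does **not** emulate: demographic covariates (age, sex,
mobility) and their effects on activity, weekday/weekend differences,
external-motion artifacts (car journeys), device miscalibration, and raw
32-Hz accelerations (counts are generated directly at epoch level).  Passing
tests therefore validate the pipeline's statistical machinery on data with
the right structure and scale, not the full messiness of clinical
recordings.

## Validation problem sizes

The test-suite and `scripts/acceptance.py` validate at sizes chosen to give
stable statistical verdicts at interactive cost: M10 against a brute-force
scan on 50 random profiles in both wraparound modes; Fourier round-trips on
20 low-harmonic profiles (machine-precision recovery); permutation
exactness on a 3-vs-3 toy (20 relabelings, enumerated by hand in the test,
with the 5000-draw Monte-Carlo p checked against its exact binomial 99%
interval); family-wise type-I calibration over 200 null-cohort pipeline runs
(8+8 subjects × 5 days, 500 permutations, α = 0.05) against the exact
binomial 95% band; effect recovery over 50 cohort runs (10+10 subjects ×
7 days, multiplier 1.5, α = 0.006) requiring temporal Jaccard ≥ 0.5 with the
injected windows in ≥ 80% of runs; and per-epoch removal detection on a
20-subject cohort requiring sensitivity ≥ 0.95 and specificity ≥ 0.99
against the truth manifest.

## Known limitations

* The finite Fourier basis rings: a square-wave group effect leaks small
  systematic differences into the night, where between-subject variance is
  lowest, so short spurious significant intervals near midnight can
  accompany genuine daytime detections (visible in the worked example).
  This is a property of basis-truncation FLM generally, not of this
  implementation.
* Exact enumeration is all-subsets, so it engages only for small cohorts
  (the auto rule: number of distinct relabelings ≤ requested permutations).
* Imputation assumes missingness is unrelated to activity level given clock
  time (removal for bathing/swimming approximates this; diary-omitted
  removals on valid days are still rule-detected before imputation).
* The cleaning stage order is a reconstruction of a protocol whose full
  staged specification is not public; the thresholds themselves are as
  published.
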