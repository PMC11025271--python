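"""Cleaning protocol: removal detection, day validity, imputation, inclusion.

Fixtures bracket every protocol threshold (10-min wake rule, 120-min sleep
rule, 3-h day rule, 5-day subject rule, zero-donor imputation) so detection
and exclusion behaviour is pinned exactly at the boundaries.
"""

import numpy as np
import pytest

from actiprofile.cleaning import (
    CleaningConfig,
    RemovalInterval,
    UnimputableError,
    apply_protocol,
    classify_day_validity,
    detect_removal_intervals,
    detect_systematic_error,
    impute_removals,
    include_subject,
    merge_intervals,
)
from actiprofile.io import align_to_epochs

from conftest import EPD, START_DATE, flat_days, make_series, standard_diary

MIN = 2  # epochs per minute


def _zero_run(counts, day, start_hour, minutes):
    i0 = int(day * EPD + start_hour * 120)
    counts[i0:i0 + minutes * MIN] = 0
    return i0, i0 + minutes * MIN


class TestWakeRule:
    def test_12_min_wake_run_detected(self):
        counts = flat_days(1)
        i0, i1 = _zero_run(counts, 0, 10.0, 12)
        series = make_series(counts)
        states = align_to_epochs(standard_diary(1), series)
        found = detect_removal_intervals(series, states)
        assert [(r.start, r.end, r.source) for r in found] == [(i0, i1, "wake_rule")]
        assert found[0].n_epochs == 24

    def test_9_min_wake_run_not_detected(self):
        counts = flat_days(1)
        _zero_run(counts, 0, 10.0, 9)
        series = make_series(counts)
        states = align_to_epochs(standard_diary(1), series)
        assert detect_removal_intervals(series, states) == []

    def test_sedentary_overlap_splits_run(self):
        # 12-min zero run 10:00-10:12; sedentary 10:00-10:05 leaves a 7-min
        # wake-only remainder, below the 10-min rule
        counts = flat_days(1)
        _zero_run(counts, 0, 10.0, 12)
        series = make_series(counts)
        diary = standard_diary(1, sedentary_0=[(10.0, 10.0 + 5 / 60)])
        states = align_to_epochs(diary, series)
        assert detect_removal_intervals(series, states) == []

    def test_zero_run_on_no_diary_day_not_detected(self):
        counts = flat_days(2)
        _zero_run(counts, 1, 10.0, 30)
        series = make_series(counts)
        states = align_to_epochs(standard_diary(1), series)  # day 1 uncovered
        assert detect_removal_intervals(series, states) == []


class TestSleepRule:
    def test_sleep_threshold_bracketing(self):
        for minutes, expect in [(90, 0), (130, 1)]:
            counts = flat_days(2)
            _zero_run(counts, 0, 22.0, minutes)  # inside night (21:00 onset)
            series = make_series(counts)
            states = align_to_epochs(standard_diary(2), series)
            found = detect_removal_intervals(series, states)
            assert len(found) == expect, f"{minutes}-min run"
            if expect:
                assert found[0].source == "sleep_rule"

    def test_nap_counts_as_sleep_for_long_rule(self):
        counts = flat_days(1)
        # zero run exactly covering a 125-min nap
        i0, i1 = _zero_run(counts, 0, 12.0, 125)
        series = make_series(counts)
        diary = standard_diary(1, naps_0=[(12.0, 12.0 + 125 / 60)])
        states = align_to_epochs(diary, series)
        found = detect_removal_intervals(series, states)
        assert [(r.start, r.end) for r in found] == [(i0, i1)]


class TestSystematicError:
    def test_normal_sleep_no_flags(self):
        series = make_series(flat_days(3))
        assert detect_systematic_error(series) == []

    def test_constant_activity_flags_both_days(self):
        # 30 h of strictly positive counts spanning two calendar days
        counts = flat_days(2)
        counts[int(18 * 120): int(48 * 120)] = 50.0
        series = make_series(counts)
        from datetime import timedelta
        assert detect_systematic_error(series) == [START_DATE, START_DATE + timedelta(days=1)]

    def test_short_series_without_rest_flags_all_days(self):
        series = make_series(np.full(12 * 120, 30.0))  # 12 h, no rest
        assert detect_systematic_error(series) == [START_DATE]


class TestDayValidity:
    @pytest.mark.parametrize("minutes,expect_valid,reason", [
        (179, True, None), (181, False, "removal_ge_3h"),
    ])
    def test_three_hour_bracketing(self, minutes, expect_valid, reason):
        series = make_series(flat_days(1))
        removals = [RemovalInterval(8 * 120, 8 * 120 + minutes * MIN, "diary")]
        reports = classify_day_validity(series, removals, standard_diary(1))
        assert len(reports) == 1
        assert reports[0].valid is expect_valid
        assert reports[0].exclusion_reason == reason
        assert reports[0].removal_minutes == minutes

    def test_missing_diary_invalidates(self):
        series = make_series(flat_days(1))
        reports = classify_day_validity(series, [], [])
        assert not reports[0].valid and reports[0].exclusion_reason == "no_diary"

    def test_partial_days_invalid(self):
        # 42 h starting at noon: partial day, full day, partial day
        from conftest import dt
        series = make_series(np.full(42 * 120, 50.0), start=dt(0, 12.0))
        reports = classify_day_validity(series, [], standard_diary(2))
        assert [r.exclusion_reason for r in reports] == ["partial_day", None, "partial_day"]

    def test_removal_minutes_conservation(self, rng):
        series = make_series(flat_days(4))
        raw = [RemovalInterval(int(a), int(a) + int(d), "diary")
               for a, d in zip(rng.integers(0, 4 * EPD - 400, 8), rng.integers(20, 400, 8))]
        merged = merge_intervals(raw)
        reports = classify_day_validity(series, merged, standard_diary(4))
        total = sum(r.n_epochs for r in merged) / MIN
        assert sum(rep.removal_minutes for rep in reports) == pytest.approx(total)


class TestImputation:
    def _three_day_series(self):
        counts = flat_days(3)
        # clock 10:00 on days 0,1,2 -> values 10, 20, then removed on day 2
        counts[int(10 * 120)] = 10
        counts[int(EPD + 10 * 120)] = 20
        return counts

    def test_donor_mean(self):
        counts = self._three_day_series()
        i = int(2 * EPD + 10 * 120)
        series = make_series(counts)
        removals = [RemovalInterval(i, i + 1, "diary")]
        reports = classify_day_validity(series, removals, standard_diary(3))
        out = impute_removals(series, removals, reports)
        assert out.counts[i] == pytest.approx(15.0)
        assert out.flags[i] == "imputed"
        # everything outside the removal is bit-identical
        mask = np.ones(series.n_epochs, dtype=bool)
        mask[i] = False
        np.testing.assert_array_equal(out.counts[mask], series.counts[mask])

    def test_no_removals_identity(self):
        series = make_series(self._three_day_series())
        out = impute_removals(series, [], classify_day_validity(series, [], standard_diary(3)))
        np.testing.assert_array_equal(out.counts, series.counts)
        assert not np.any(out.flags == "imputed")

    def test_zero_donor_raises(self):
        series = make_series(flat_days(2))
        # same clock hour removed on both valid days
        removals = [RemovalInterval(int(10 * 120), int(10 * 120) + 2, "diary"),
                    RemovalInterval(int(EPD + 10 * 120), int(EPD + 10 * 120) + 2, "diary")]
        reports = classify_day_validity(series, removals, standard_diary(2))
        with pytest.raises(UnimputableError):
            impute_removals(series, removals, reports)


class TestProtocol:
    def test_clean_fixture_identity(self):
        series = make_series(flat_days(7))
        cleaned, reports, removals = apply_protocol(series, standard_diary(7))
        assert removals == []
        assert all(r.valid for r in reports) and len(reports) == 7
        np.testing.assert_array_equal(cleaned.counts, series.counts)

    def test_known_artifacts(self):
        # one day with a 4-h diary removal, another with a 20-min wake zero run
        counts = flat_days(7)
        _zero_run(counts, 2, 9.0, 240)   # 4 h -> day 2 invalid
        _zero_run(counts, 4, 15.0, 20)   # 20 min -> wake rule, imputed
        series = make_series(counts)
        diary = standard_diary(7, removals_2=[(9.0, 13.0)])
        cleaned, reports, removals = apply_protocol(series, diary)
        assert sum(r.valid for r in reports) == 6
        assert [r.exclusion_reason for r in reports if not r.valid] == ["removal_ge_3h"]
        assert sorted(r.source for r in removals) == ["diary", "wake_rule"]
        assert int(np.sum(cleaned.flags == "imputed")) == 40
        assert cleaned.n_epochs == 6 * EPD

    def test_idempotent_on_own_output(self):
        counts = flat_days(5)
        _zero_run(counts, 1, 15.0, 20)
        series = make_series(counts)
        cleaned, reports, _ = apply_protocol(series, standard_diary(5))
        valid_dates = {r.date for r in reports if r.valid}
        diary2 = [d for d in standard_diary(5) if d.date in valid_dates
                  or d.date < min(valid_dates)]
        cleaned2, reports2, removals2 = apply_protocol(cleaned, diary2)
        assert all(r.valid for r in reports2)
        np.testing.assert_array_equal(cleaned2.counts, cleaned.counts)


class TestSubjectInclusion:
    @pytest.mark.parametrize("n_valid,expect", [(5, True), (4, False)])
    def test_five_day_rule(self, n_valid, expect):
        series = make_series(flat_days(7))
        diary = standard_diary(n_valid)  # remaining days lack diary rows
        _, reports, _ = apply_protocol(series, diary)
        included, diag = include_subject(reports)
        assert included is expect
        assert diag["n_valid_days"] == n_valid

    def test_weekend_diagnostic(self):
        # START_DATE is a Monday: 5 valid weekdays, no weekend
        series = make_series(flat_days(5))
        _, reports, _ = apply_protocol(series, standard_diary(5))
        included, diag = include_subject(reports)
        assert included
        assert diag["weekday_criterion_met"] and not diag["weekend_criterion_met"]
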