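"""Fourier fitting, pointwise F statistics and the permutation F-test."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from actiprofile.circadian import AverageDayProfile
from actiprofile.flm import (
    FourierBasisConfig,
    PermutationConfig,
    SleepWindow,
    SubjectCurve,
    annotate_sleep_overlap,
    evaluate_curve,
    fit_fourier,
    fourier_design,
    permutation_f_test,
    pointwise_f,
    temporal_jaccard,
)
from actiprofile.io import ValidationError


def profile_from(values, resolution=60):
    return AverageDayProfile(grid_resolution=resolution,
                             values=np.asarray(values, dtype=float), n_days=1)


def harmonic_profile(coef, resolution=60):
    n = 86400 // resolution
    t = np.arange(n) * resolution / 3600.0
    return fourier_design(t, len(coef)) @ np.asarray(coef, dtype=float)


class TestFourierFit:
    def test_recovers_single_cosine(self):
        values = harmonic_profile([100.0, 0.0, 50.0])
        coef = fit_fourier(profile_from(values)).coefficients
        expected = np.array([100.0, 0, 50.0, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(coef, expected, atol=1e-8 * 100)

    def test_constant_profile(self):
        coef = fit_fourier(profile_from(np.full(1440, 42.0))).coefficients
        np.testing.assert_allclose(coef, [42.0] + [0.0] * 8, atol=1e-10)

    def test_four_harmonic_zero_residual(self, rng):
        true = rng.normal(0, 30, size=9)
        true[0] = 300.0
        values = harmonic_profile(true)
        curve = fit_fourier(profile_from(values))
        np.testing.assert_allclose(curve.coefficients, true, rtol=1e-10, atol=1e-10)
        recon = evaluate_curve(curve, 1440)
        np.testing.assert_allclose(recon, values, atol=1e-8)

    def test_refit_idempotent(self, rng):
        values = rng.gamma(2.0, 80.0, size=1440)
        c1 = fit_fourier(profile_from(values))
        c2 = fit_fourier(profile_from(evaluate_curve(c1, 1440)))
        np.testing.assert_allclose(c2.coefficients, c1.coefficients, rtol=1e-9, atol=1e-9)

    def test_residual_orthogonal_to_basis(self, rng):
        values = rng.gamma(2.0, 80.0, size=1440)
        curve = fit_fourier(profile_from(values))
        t = np.arange(1440) / 60.0
        design = fourier_design(t, 9)
        resid = values - design @ curve.coefficients
        np.testing.assert_allclose(design.T @ resid, 0.0, atol=1e-6)

    def test_even_basis_rejected(self):
        with pytest.raises(ValidationError):
            FourierBasisConfig(n_basis=8)


class TestEvaluate:
    def test_zero_and_constant(self):
        assert np.all(evaluate_curve(SubjectCurve(np.zeros(9)), 100) == 0)
        np.testing.assert_allclose(evaluate_curve(SubjectCurve([1] + [0] * 8), 100), 1.0)

    def test_periodicity(self, rng):
        curve = SubjectCurve(rng.normal(size=9))
        v0 = evaluate_curve(curve, np.array([0.0]))
        v24 = evaluate_curve(curve, np.array([1440.0]))
        assert v0[0] == pytest.approx(v24[0])


def constant_curves(values):
    return [SubjectCurve([v] + [0.0] * 8) for v in values]


class TestPointwiseF:
    def test_identical_groups_zero(self):
        a = constant_curves([1.0, 2.0, 3.0])
        f = pointwise_f(a, constant_curves([1.0, 2.0, 3.0]), grid=48)
        np.testing.assert_allclose(f, 0.0, atol=1e-20)

    def test_hand_computed_two_plus_two(self):
        # groups {0,1} vs {2,3}: SSB=4, MSW=0.5 -> F=8 at every t
        f = pointwise_f(constant_curves([0.0, 1.0]), constant_curves([2.0, 3.0]), grid=24)
        np.testing.assert_allclose(f, 8.0)

    def test_equals_squared_t(self, rng):
        a = [SubjectCurve(rng.normal(0, 10, 9)) for _ in range(5)]
        b = [SubjectCurve(rng.normal(0, 10, 9)) for _ in range(7)]
        grid = 96
        f = pointwise_f(a, b, grid=grid)
        va = np.vstack([evaluate_curve(c, grid) for c in a])
        vb = np.vstack([evaluate_curve(c, grid) for c in b])
        t = sps.ttest_ind(va, vb, axis=0).statistic
        np.testing.assert_allclose(f, t**2, rtol=1e-9)

    def test_degenerate_variance_contract(self):
        f = pointwise_f(constant_curves([1.0, 1.0]), constant_curves([2.0, 2.0]), grid=12)
        assert np.all(np.isinf(f))
        f0 = pointwise_f(constant_curves([1.0, 1.0]), constant_curves([1.0, 1.0]), grid=12)
        assert np.all(f0 == 0.0)


class TestPermutationTest:
    def _toy(self, rng, shift=50.0, n=3):
        base = np.array([100.0] + [0.0] * 8)
        a = [SubjectCurve(base + rng.normal(0, 1, 9)) for _ in range(n)]
        offset = np.array([shift] + [0.0] * 8)
        b = [SubjectCurve(base + offset + rng.normal(0, 1, 9)) for _ in range(n)]
        return a + b, ["A"] * n + ["B"] * n

    def test_exchangeable_null_p_is_one(self):
        curves = constant_curves([5.0, 5.0, 5.0, 5.0])
        labels = ["A", "A", "B", "B"]
        res = permutation_f_test(curves, labels, grid=48,
                                 perm_config=PermutationConfig(n_permutations=100, seed=1))
        assert res.p_global == 1.0
        assert res.significant_intervals == []

    def test_exact_enumeration_matches_hand_enumeration(self, rng):
        curves, labels = self._toy(rng)
        cfg = PermutationConfig(n_permutations=5000, alpha=0.05, seed=3, method="exact")
        res = permutation_f_test(curves, labels, grid=144, perm_config=cfg)
        assert res.method == "exact" and res.n_permutations == 20

        # independent enumeration over all C(6,3) relabelings
        data = np.vstack([evaluate_curve(c, 144) for c in curves])
        maxes = []
        for combo in itertools.combinations(range(6), 3):
            ga = data[list(combo)]
            gb = data[[i for i in range(6) if i not in combo]]
            f = sps.f_oneway(ga, gb, axis=0).statistic
            maxes.append(np.nanmax(f))
        obs = max(maxes[0], 0)  # combo (0,1,2) is the observed labeling
        maxes = np.array(maxes)
        # a split and its complement give the same F analytically; tolerate
        # float-level asymmetry when counting the >= tie
        expected_p = np.mean((maxes >= obs) | np.isclose(maxes, obs, rtol=1e-9))
        assert res.p_global == pytest.approx(expected_p)

    def test_auto_switches_to_exact(self, rng):
        curves, labels = self._toy(rng)
        res = permutation_f_test(curves, labels, grid=48,
                                 perm_config=PermutationConfig(n_permutations=5000, seed=0))
        assert res.method == "exact"

    def test_seed_reproducible_and_order_invariant(self, rng):
        curves = [SubjectCurve(rng.normal(0, 5, 9)) for _ in range(12)]
        labels = ["A"] * 6 + ["B"] * 6
        cfg = PermutationConfig(n_permutations=200, seed=11, method="monte_carlo")
        r1 = permutation_f_test(curves, labels, grid=96, perm_config=cfg)
        perm = list(rng.permutation(12))
        r2 = permutation_f_test([curves[i] for i in perm], [labels[i] for i in perm],
                                grid=96, perm_config=cfg)
        assert r1.p_global == r2.p_global
        assert r1.max_critical == r2.max_critical
        np.testing.assert_array_equal(r1.f_observed, r2.f_observed)
        np.testing.assert_array_equal(r1.pointwise_critical, r2.pointwise_critical)

    def test_pointwise_never_exceeds_max_critical(self, rng):
        curves = [SubjectCurve(rng.normal(0, 5, 9)) for _ in range(10)]
        labels = ["A"] * 5 + ["B"] * 5
        res = permutation_f_test(curves, labels, grid=96,
                                 perm_config=PermutationConfig(n_permutations=300, seed=2))
        assert np.all(res.pointwise_critical <= res.max_critical + 1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            permutation_f_test(constant_curves([1.0, 2.0, 3.0]), ["A", "B", "B"], grid=24)


class TestSleepOverlap:
    windows = (SleepWindow("high", mean_sleep_offset=7 + 4 / 60, mean_sleep_onset=20 + 4 / 60),
               SleepWindow("low", mean_sleep_offset=6 + 10 / 60, mean_sleep_onset=21.0))

    def _result_with(self, intervals):
        from actiprofile.flm import PermutationFResult
        return PermutationFResult(
            grid_minutes=np.arange(1440.0), f_observed=np.zeros(1440),
            max_critical=1.0, pointwise_critical=np.zeros(1440),
            significant_intervals=intervals, p_global=1.0, alpha=0.05,
            method="monte_carlo", n_permutations=1)

    def test_daytime_interval_is_wake_only(self):
        out = annotate_sleep_overlap(self._result_with([(13 * 60.0, 15.5 * 60.0)]), self.windows)
        assert out[0]["label"] == "wake_only"

    def test_early_interval_precedes_offset(self):
        out = annotate_sleep_overlap(self._result_with([(5 * 60 + 20.0, 6 * 60.0)]), self.windows)
        assert out[0]["label"] == "overlaps_sleep"
        assert any(b.startswith("precedes_offset") for b in out[0]["boundaries"])

    def test_empty_intervals(self):
        assert annotate_sleep_overlap(self._result_with([]), self.windows) == []


class TestTemporalJaccard:
    def test_identical_intervals(self):
        assert temporal_jaccard([(60, 120)], [(60, 120)]) == pytest.approx(1.0)

    def test_half_overlap(self):
        assert temporal_jaccard([(0, 60)], [(30, 90)]) == pytest.approx(1 / 3)

    def test_empty_both(self):
        assert temporal_jaccard([], []) == 1.0
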