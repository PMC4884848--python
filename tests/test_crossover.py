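"""Two-limb piecewise fitting, crossover location and angle."""

import numpy as np
import pytest

from cgmdfa import (
    NoCrossoverError,
    PiecewiseFit,
    angle_of,
    angle_of_slopes,
    best_fit,
    candidate_splits,
    crossover_of,
    fit_split,
    fluctuation_curve,
)
from cgmdfa.dfa import WINDOW_POINTS, FluctuationCurve
from oracles import best_split_bruteforce, limb_r2_bruteforce

LOG_X = np.log(np.asarray(WINDOW_POINTS, dtype=float))


def two_line_curve(k, slope1=1.5, slope2=0.35, intercept1=-3.0):
    """A 16-point curve lying exactly on two lines meeting between
    points k and k+1 (1-based)."""
    x_break = 0.5 * (LOG_X[k - 1] + LOG_X[k])
    intercept2 = intercept1 + (slope1 - slope2) * x_break
    log_y = np.where(
        np.arange(16) < k, intercept1 + slope1 * LOG_X, intercept2 + slope2 * LOG_X
    )
    return FluctuationCurve(window_points=np.asarray(WINDOW_POINTS), fn=np.exp(log_y))


class TestCandidateSplits:
    def test_default_16_point_curve_has_8_candidates(self):
        assert candidate_splits(16, 4, 5) == [4, 5, 6, 7, 8, 9, 10, 11]

    def test_boundary_single_candidate(self):
        assert candidate_splits(9, 4, 5) == [4]

    def test_too_short_curve_errors(self):
        with pytest.raises(ValueError, match="too short"):
            candidate_splits(8, 4, 5)


class TestFitSplit:
    def test_exact_two_line_data_recovered_at_true_split(self):
        curve = two_line_curve(9, slope1=1.5, slope2=0.35)
        fit = fit_split(curve, 9)
        assert fit.slope1 == pytest.approx(1.5, abs=1e-10)
        assert fit.slope2 == pytest.approx(0.35, abs=1e-10)
        assert fit.r2_combined == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_have_unit_r2_and_no_crossover(self):
        pts = np.asarray(WINDOW_POINTS)
        curve = FluctuationCurve(window_points=pts, fn=pts.astype(float) ** 0.9)
        fit = fit_split(curve, 7)
        assert fit.slope1 == pytest.approx(fit.slope2, abs=1e-12)
        assert fit.r2_combined == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(fit.crossover_minutes)
        with pytest.raises(NoCrossoverError):
            crossover_of(fit)

    def test_limb_r2_matches_explicit_sum_oracle(self):
        rng = np.random.default_rng(7)
        log_y = 0.8 * LOG_X + rng.standard_normal(16) * 0.3
        curve = FluctuationCurve(
            window_points=np.asarray(WINDOW_POINTS), fn=np.exp(log_y)
        )
        for k in (4, 8, 11):
            fit = fit_split(curve, k)
            r1 = limb_r2_bruteforce(LOG_X[:k], log_y[:k])
            r2 = limb_r2_bruteforce(LOG_X[k:], log_y[k:])
            assert fit.r2_combined == pytest.approx(
                (k * r1 + (16 - k) * r2) / 16, rel=1e-10
            )


class TestBestFit:
    @pytest.mark.parametrize("k", [4, 5, 6, 7, 8, 9, 10, 11])
    def test_exact_recovery_at_every_candidate_split(self, k):
        curve = two_line_curve(k)
        fit = best_fit(curve)
        assert fit.split_index == k
        assert fit.slope1 == pytest.approx(1.5, abs=1e-10)
        assert fit.slope2 == pytest.approx(0.35, abs=1e-10)
        assert fit.r2_combined == pytest.approx(1.0, abs=1e-12)

    def test_single_line_ties_break_to_smallest_split(self):
        pts = np.asarray(WINDOW_POINTS)
        curve = FluctuationCurve(window_points=pts, fn=pts.astype(float) ** 0.9)
        assert best_fit(curve).split_index == 4

    def test_agrees_with_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            log_y = 1.2 * LOG_X - 2.0 + 0.2 * rng.standard_normal(16)
            curve = FluctuationCurve(
                window_points=np.asarray(WINDOW_POINTS), fn=np.exp(log_y)
            )
            fit = best_fit(curve)
            k_ref, r2_ref = best_split_bruteforce(LOG_X, log_y, range(4, 12))
            assert fit.split_index == k_ref
            assert fit.r2_combined == pytest.approx(r2_ref, rel=1e-10)

    def test_modal_split_recovered_under_small_noise(self):
        rng = np.random.default_rng(13)
        true_k = 9
        recovered = []
        for _ in range(50):
            curve = two_line_curve(true_k)
            noisy = np.exp(np.log(curve.fn) + 0.01 * rng.standard_normal(16))
            fit = best_fit(
                FluctuationCurve(window_points=curve.window_points, fn=noisy)
            )
            recovered.append(fit.split_index)
        values, counts = np.unique(recovered, return_counts=True)
        assert values[np.argmax(counts)] == true_k

    def test_crossover_invariant_under_glucose_scaling(self, make_series):
        rng = np.random.default_rng(17)
        values = 6.0 + 0.8 * rng.standard_normal(288)
        fit_a = best_fit(fluctuation_curve(make_series(values)))
        fit_b = best_fit(fluctuation_curve(values * 18.016))
        assert fit_a.crossover_minutes == pytest.approx(
            fit_b.crossover_minutes, rel=1e-9
        )
        assert fit_a.angle_rad == pytest.approx(fit_b.angle_rad, abs=1e-10)


class TestCrossoverConversion:
    def test_log24_maps_to_120_minutes(self):
        fit = PiecewiseFit(
            split_index=8,
            slope1=1.0,
            slope2=0.0,
            intercept1=0.0,
            intercept2=np.log(24.0),
            r2_combined=1.0,
        )
        assert crossover_of(fit) == pytest.approx(120.0, rel=1e-12)

    def test_cohort_scale_conversion(self):
        # x = ln(22.8) window points corresponds to ~114 min at 5-min sampling
        fit = PiecewiseFit(
            split_index=8,
            slope1=1.0,
            slope2=0.0,
            intercept1=0.0,
            intercept2=np.log(22.8),
            r2_combined=1.0,
        )
        assert crossover_of(fit) == pytest.approx(114.0, rel=1e-12)

    def test_parallel_limbs_raise(self):
        fit = PiecewiseFit(
            split_index=8,
            slope1=0.5,
            slope2=0.5,
            intercept1=0.0,
            intercept2=1.0,
            r2_combined=1.0,
        )
        with pytest.raises(NoCrossoverError, match="no crossover"):
            crossover_of(fit)


class TestAngle:
    def test_cohort_median_slopes_give_cohort_median_angle(self):
        # arctan(1.53) - arctan(0.36) = 0.646 rad
        assert angle_of_slopes(1.53, 0.36) == pytest.approx(0.646, abs=1e-3)

    def test_equal_slopes_give_zero(self):
        assert angle_of_slopes(0.8, 0.8) == 0.0

    def test_antisymmetry(self):
        assert angle_of_slopes(1.2, 0.3) == pytest.approx(
            -angle_of_slopes(0.3, 1.2), rel=1e-12
        )

    def test_angle_of_fit_positive_when_first_limb_steeper(self):
        curve = two_line_curve(8, slope1=1.5, slope2=0.35)
        fit = best_fit(curve)
        angle = angle_of(fit)
        assert 0 < angle < np.pi
        assert angle == pytest.approx(np.arctan(1.5) - np.arctan(0.35), abs=1e-9)
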