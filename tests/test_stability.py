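"""Stability index, trajectory reconstruction, and decay-kinetics fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from encapkin import (
    DecaySeries,
    average_r_squared,
    compute_stability,
    detect_rate_peak,
    fit_first_order,
    fit_zero_order,
    reconstruct_trajectory,
)
from encapkin.exceptions import DegenerateDesignError, InsufficientDataError
from encapkin.stability import KineticFit


class TestStabilityIndex:
    @pytest.mark.parametrize(
        "a_t, a_0, expected",
        [
            (145.1, 145.1, 100.0),
            (137.845, 145.1, 95.0),  # fresh-emulsion spot value, day 1 at 5 degC
            (0.0, 100.0, 0.0),
            (120.0, 100.0, 120.0),  # day-2 recoveries exceed 100 and are not capped
        ],
    )
    def test_percent_ratio(self, a_t, a_0, expected):
        assert compute_stability(a_t, a_0) == pytest.approx(expected, abs=1e-9)

    def test_undefined_ratio(self):
        with pytest.raises(ValueError):
            compute_stability(50.0, 0.0)
        with pytest.raises(ValueError):
            compute_stability(-1.0, 100.0)


class TestReconstruction:
    def test_pure_xanthan_cold_trajectory(self):
        # activity 233 AU with daily percents 72/48/36 -> absolute absorbance
        s = reconstruct_trajectory(233, [72, 48, 36])
        assert s.times.tolist() == [0, 1, 2, 3]
        assert s.values == pytest.approx([233.0, 167.76, 111.84, 83.88])

    def test_constant_percents_give_constant_series(self):
        s = reconstruct_trajectory(100, [100, 100])
        assert s.values == pytest.approx([100.0, 100.0, 100.0])

    def test_round_trip_is_algebraic_inverse(self):
        pct = [95.0, 73.2, 33.3]
        s = reconstruct_trajectory(145.1, pct)
        back = [compute_stability(v, s.values[0]) for v in s.values[1:]]
        assert back == pytest.approx(pct, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            reconstruct_trajectory(0.0, [50.0])
        with pytest.raises(ValueError):
            reconstruct_trajectory(100.0, [-5.0])


class TestZeroOrderFit:
    def test_exact_line(self):
        s = DecaySeries([0, 1, 2, 3], [100, 90, 80, 70])
        fit = fit_zero_order(s)
        assert fit.intercept == pytest.approx(100.0)
        assert fit.signed_rate == pytest.approx(-10.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_xanthan_cold_matches_published_fit(self):
        # published intercept/slope 225 / -50; OLS on reconstructed means
        fit = fit_zero_order(reconstruct_trajectory(233, [72, 48, 36]))
        assert fit.intercept == pytest.approx(225.0, rel=0.01)
        assert fit.signed_rate == pytest.approx(-50.0, rel=0.01)

    def test_matches_normal_equations_oracle(self, rng):
        t = np.sort(rng.uniform(0, 5, 6))
        y = 150 - 20 * t + rng.normal(0, 5, 6)
        fit = fit_zero_order(DecaySeries(t, y))
        # closed-form normal-equations solution
        A = np.column_stack([np.ones(6), t])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        ssr_fit = np.sum((y - fit.predict(t)) ** 2)
        ssr_oracle = np.sum((y - A @ beta) ** 2)
        assert abs(ssr_fit - ssr_oracle) < 1e-10

    def test_saturated_two_point_fit_r2_is_exactly_one(self):
        fit = fit_zero_order(DecaySeries([0, 1], [10.0, 7.0]))
        assert fit.r_squared == 1.0
        assert fit.se_rate == 0.0  # no residual degrees of freedom

    def test_degenerate_design(self):
        with pytest.raises((DegenerateDesignError, ValueError)):
            fit_zero_order(DecaySeries([2.0], [5.0]))

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.1, 10),
    )
    def test_affine_invariance(self, shift, scale):
        t = np.array([0.0, 1, 2, 3])
        y = np.array([200.0, 151, 118, 64])
        base = fit_zero_order(DecaySeries(t, y))
        moved = fit_zero_order(DecaySeries(t, scale * y + shift))
        assert moved.intercept == pytest.approx(scale * base.intercept + shift, rel=1e-9)
        assert moved.rate == pytest.approx(scale * base.rate, rel=1e-9)
        assert moved.r_squared == pytest.approx(base.r_squared, abs=1e-9)


class TestFirstOrderFit:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(4.0)
        s = DecaySeries(t, 200 * np.exp(-0.3 * t))
        fit = fit_first_order(s)
        assert fit.intercept == pytest.approx(200.0, rel=1e-6)
        assert fit.rate == pytest.approx(0.3, rel=1e-6)
        assert fit.direction == "decay"

    def test_pure_xanthan_cold_within_published_uncertainty(self):
        # published 234 +- 5 and -0.34 +- 0.02
        fit = fit_first_order(reconstruct_trajectory(233, [72, 48, 36]))
        assert abs(fit.intercept - 234) <= 5
        assert abs(fit.signed_rate - (-0.34)) <= 0.02

    def test_beats_grid_search_oracle(self, rng):
        t = np.arange(5.0)
        y = 180 * np.exp(-0.4 * t) + rng.normal(0, 3, 5)
        fit = fit_first_order(DecaySeries(t, y))
        ssr_fit = np.sum((y - fit.predict(t)) ** 2)
        p0_grid = np.linspace(100, 260, 200)
        k_grid = np.linspace(0.05, 1.0, 200)
        preds = p0_grid[:, None, None] * np.exp(-k_grid[None, :, None] * t)
        ssr_grid = np.sum((preds - y) ** 2, axis=2).min()
        assert ssr_fit <= ssr_grid + 1e-10

    @given(
        k=st.floats(0.01, 2.0),
        p0=st.floats(10.0, 1000.0),
    )
    def test_noiseless_recovery_over_parameter_space(self, k, p0):
        t = np.arange(4.0)
        fit = fit_first_order(DecaySeries(t, p0 * np.exp(-k * t)))
        assert fit.intercept == pytest.approx(p0, rel=1e-6)
        assert fit.rate == pytest.approx(k, rel=1e-6)

    def test_requires_positive_values(self):
        with pytest.raises(ValueError):
            fit_first_order(DecaySeries([0, 1, 2], [5.0, 0.0, -1.0]))

    def test_requires_three_points(self):
        with pytest.raises(InsufficientDataError):
            fit_first_order(DecaySeries([0, 1], [5.0, 4.0]))


class TestSummaries:
    def test_average_r_squared_of_published_fits(self, kinetic_fits_table):
        zero = [
            KineticFit(0, i, abs(s), "decay", 0, 0, r)
            for i, s, r in kinetic_fits_table[
                ["zero_intercept", "zero_slope", "zero_r2"]
            ].itertuples(index=False)
        ]
        first = [
            KineticFit(1, i, abs(s), "decay", 0, 0, r)
            for i, s, r in kinetic_fits_table[
                ["first_intercept", "first_slope", "first_r2"]
            ].itertuples(index=False)
        ]
        assert round(average_r_squared(zero), 3) == 0.891
        assert round(average_r_squared(first), 3) == 0.893

    def test_trivial_average(self):
        fits = [KineticFit(0, 100, 10, "decay", 0, 0, 0.9)] * 3
        assert average_r_squared(fits) == pytest.approx(0.9)

    def test_empty_and_mixed_collections_rejected(self):
        with pytest.raises(ValueError):
            average_r_squared([])
        mixed = [
            KineticFit(0, 1, 1, "decay", 0, 0, 0.5),
            KineticFit(1, 1, 1, "decay", 0, 0, 0.5),
        ]
        with pytest.raises(ValueError):
            average_r_squared(mixed)


class TestRatePeak:
    @pytest.mark.parametrize(
        "rates, expected",
        [
            ({5: 38, 20: 55, 35: 34}, "peaked"),  # mid-temperature maximum
            ({5: 10, 20: 20, 35: 30}, "monotone"),
            ({5: 49, 20: 49, 35: 49}, "flat"),
        ],
    )
    def test_classification(self, rates, expected):
        assert detect_rate_peak(rates) == expected

    def test_needs_three_temperatures(self):
        with pytest.raises(InsufficientDataError):
            detect_rate_peak({5: 1.0, 20: 2.0})
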