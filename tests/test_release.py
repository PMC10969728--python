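"""Release-curve processing and the two effective-diffusivity routes."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from encapkin import (
    DecaySeries,
    SimulationConfig,
    fit_fickian_truncated,
    fit_first_order_release,
    gen_release_curve,
    k_to_diffusivity,
    normalize_release,
    series_remaining_fraction,
    trim_at_plateau,
    truncated_remaining_fraction,
)
from encapkin.exceptions import InsufficientDataError
from encapkin.release import MonolithGeometry, estimate_diffusivities


def series(values, dt=1.0):
    v = np.asarray(values, dtype=float)
    return DecaySeries(np.arange(v.size) * dt, v, time_unit="s")


class TestPlateauTrimming:
    def test_flat_tail_is_cut(self):
        s = series([10, 9, 8, 8.0001, 8.0000, 8.0001])
        assert len(trim_at_plateau(s, tolerance=0.001)) == 4

    def test_strictly_decreasing_series_unchanged(self):
        s = series([10, 9, 8, 7, 6])
        assert len(trim_at_plateau(s, tolerance=0.001)) == 5

    def test_constant_series_keeps_three_points(self):
        s = series([5.0] * 6)
        assert len(trim_at_plateau(s, tolerance=0.001)) == 3

    def test_needs_three_points(self):
        with pytest.raises(InsufficientDataError):
            trim_at_plateau(series([2.0, 1.0]))


class TestNormalization:
    def test_constant_weights_give_unity(self):
        out = normalize_release(series([6.0, 6.0, 6.0]), plateau_mass=2.0)
        assert out.values == pytest.approx([1.0, 1.0, 1.0])

    def test_linear_span(self):
        out = normalize_release(series([6.0, 5.5, 5.0]), plateau_mass=5.0)
        assert out.values == pytest.approx([1.0, 0.5, 0.0])

    def test_zero_plateau_is_pass_through(self):
        f = np.array([1.0, 0.7, 0.4])
        out = normalize_release(series(0.35 * f), plateau_mass=0.0)
        assert out.values == pytest.approx(f)

    def test_initial_weight_must_exceed_plateau(self):
        with pytest.raises(ValueError):
            normalize_release(series([5.0, 4.0, 3.0]), plateau_mass=5.0)


class TestFirstOrderRelease:
    def test_recovers_guar_formulation_rate(self):
        # per-minute rate constant 1.46e-3 used as ground truth
        t_min = np.arange(0.0, 301.0, 30.0)
        s = DecaySeries(t_min * 60, np.exp(-1.46e-3 * t_min), time_unit="s")
        fit = fit_first_order_release(s)
        assert fit.k_per_min == pytest.approx(1.46e-3, rel=1e-6)
        assert fit.m0 == pytest.approx(1.0, rel=1e-6)

    def test_constant_series_has_zero_rate(self):
        fit = fit_first_order_release(series([0.5, 0.5, 0.5, 0.5], dt=1800))
        assert fit.k == 0.0

    def test_minute_time_base(self):
        t_min = np.arange(0.0, 301.0, 30.0)
        s = DecaySeries(t_min, np.exp(-1.46e-3 * t_min), time_unit="min")
        fit = fit_first_order_release(s, time_unit="min")
        assert fit.k_per_min == pytest.approx(1.46e-3, rel=1e-6)

    def test_beats_grid_search_oracle(self, rng):
        t = np.arange(0.0, 18001.0, 1800.0)
        y = 0.6 * np.exp(-5e-5 * t) + rng.normal(0, 0.01, t.size)
        fit = fit_first_order_release(DecaySeries(t, y, time_unit="s"))
        ssr_fit = np.sum((y - fit.m0 * np.exp(-fit.k * t)) ** 2)
        m0g = np.linspace(0.3, 1.0, 200)
        kg = np.linspace(1e-5, 2e-4, 200)
        preds = m0g[:, None, None] * np.exp(-kg[None, :, None] * t)
        assert ssr_fit <= np.sum((preds - y) ** 2, axis=2).min() + 1e-12


class TestSlabRelation:
    def test_analytic_identity(self):
        assert k_to_diffusivity(math.pi**2, 1.0) == pytest.approx(1.0)
        assert k_to_diffusivity(0.0, 0.3) == 0.0

    @pytest.mark.parametrize("k_per_min, expected_1e10", [(6.69e-4, 4.5), (6.06e-4, 4.1)])
    def test_published_rates_to_diffusivity(self, k_per_min, expected_1e10):
        d = k_to_diffusivity(k_per_min / 60.0, L=0.020)
        assert float(f"{d * 1e10:.1f}") == expected_1e10  # two significant figures

    @given(k=st.floats(1e-6, 1e-2), L=st.floats(1e-3, 0.05))
    def test_linearity_in_k_and_square_law_in_L(self, k, L):
        assert k_to_diffusivity(2 * k, L) == pytest.approx(2 * k_to_diffusivity(k, L))
        assert k_to_diffusivity(k, 2 * L) == pytest.approx(4 * k_to_diffusivity(k, L))

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            k_to_diffusivity(1e-5, 0.0)
        with pytest.raises(ValueError):
            MonolithGeometry(diameter=0.0)


class TestTruncatedModel:
    def test_value_at_zero_is_truncation_artifact(self):
        assert truncated_remaining_fraction(1e-10, 0.005, 0.0) == pytest.approx(4 / math.pi)

    def test_long_time_limit_vanishes(self):
        assert truncated_remaining_fraction(1e-10, 0.005, 1e7) < 1e-6

    def test_reported_release_ratio(self):
        # fitted D_eff 2.4e-10 m^2/s over the full 5 mm thickness at 150 min
        val = truncated_remaining_fraction(2.4e-10, 0.005, 9000.0)
        assert val == pytest.approx(0.540, rel=0.01)

    @pytest.mark.parametrize("tau", [1.0, 1.5, 2.5])
    def test_one_term_matches_series_at_long_times(self, tau):
        d, L = 1e-10, 0.005
        t = tau * L**2 / (math.pi**2 * d)
        one = series_remaining_fraction(d, L, t, n_terms=1)
        full = series_remaining_fraction(d, L, t, n_terms=50)
        assert abs(one - full) < 1e-4


class TestFickianFit:
    def test_self_fit_is_exact(self):
        t = np.arange(0.0, 36001.0, 1800.0)
        s = DecaySeries(t, truncated_remaining_fraction(1e-10, 0.005, t), time_unit="s")
        est = fit_fickian_truncated(s, L=0.005)
        assert est.d_eff_fick == pytest.approx(1e-10, rel=1e-6)
        assert est.L_fick == 0.005

    def test_full_series_recovery_within_truncation_bias(self):
        cfg = SimulationConfig(
            seed=1, model="fickian_full", n_points=21, dt=1800.0, d=1e-10, L=0.005
        )
        curve = gen_release_curve(cfg)
        est = fit_fickian_truncated(curve, L=0.005, amplitude="series")
        assert est.d_eff_fick == pytest.approx(1e-10, rel=0.10)

    def test_beats_grid_search_oracle(self):
        t = np.arange(0.0, 36001.0, 1800.0)
        y = series_remaining_fraction(2e-10, 0.005, t)
        est = fit_fickian_truncated(
            DecaySeries(t, y, time_unit="s"), L=0.005, amplitude="series"
        )
        mask = est.d_eff_fick * math.pi**2 * t / 0.005**2 >= math.log(4 / math.pi)
        model = lambda D: (8 / math.pi**2) * np.exp(-D * math.pi**2 * t[mask] / 0.005**2)
        ssr_fit = np.sum((y[mask] - model(est.d_eff_fick)) ** 2)
        grid = np.linspace(0.5e-10, 5e-10, 400)
        ssr_grid = min(np.sum((y[mask] - model(D)) ** 2) for D in grid)
        assert ssr_fit <= ssr_grid + 1e-15

    def test_window_needs_three_points(self):
        t = np.array([0.0, 1800.0, 3600.0])
        s = DecaySeries(t, truncated_remaining_fraction(1e-12, 0.005, t), time_unit="s")
        with pytest.raises(InsufficientDataError):
            fit_fickian_truncated(s, L=0.005)

    def test_fitted_d_increases_when_release_accelerates(self):
        t = np.arange(0.0, 36001.0, 1800.0)
        y = series_remaining_fraction(1e-10, 0.005, t)
        slow = fit_fickian_truncated(DecaySeries(t, y, time_unit="s"), L=0.005,
                                     amplitude="series")
        fast = fit_fickian_truncated(DecaySeries(t / 2, y, time_unit="s"), L=0.005,
                                     amplitude="series")
        assert fast.d_eff_fick > slow.d_eff_fick
        assert fast.d_eff_fick == pytest.approx(2 * slow.d_eff_fick, rel=1e-6)


def test_full_pipeline_recovers_simulated_diffusivity():
    """simulate -> trim -> normalize -> first-order fit -> slab relation.

    The first-order model is a proxy for the full series, so the bound is a
    regression guard (25 %), not a physical claim.
    """
    cfg = SimulationConfig(
        seed=5, model="fickian_full", n_points=21, dt=1800.0,
        d=1e-10, L=0.005, m0=0.35, plateau_mass=5.6,
    )
    weights = gen_release_curve(cfg, as_weights=True)
    trimmed = trim_at_plateau(weights, tolerance=1e-4)
    fractions = normalize_release(trimmed, plateau_mass=5.6)
    rfit, dest = estimate_diffusivities(fractions, L_kinetic=0.005, L_fick=0.005)
    assert dest.d_from_k == pytest.approx(1e-10, rel=0.25)
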