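"""First-order inactivation kinetics and deactivation thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enzytherm import (
    DecayTimeCourse,
    bonds_broken,
    deactivation_energy,
    deactivation_params,
    deactivation_table,
    decimal_reduction,
    fit_inactivation,
    half_life,
)
from enzytherm.constants import R

LN10_OVER_LN2 = math.log(10) / math.log(2)


class TestFitInactivation:
    def test_noiseless_log_linear(self):
        t = np.array([5.0, 10, 15, 20])
        course = DecayTimeCourse(T=333.0, t=t, residual_fraction=np.exp(-0.028 * t))
        fit = fit_inactivation(course)
        assert fit.kd == pytest.approx(0.028, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points_used == 4

    def test_zero_fraction_points_excluded_and_counted(self):
        t = np.array([0.0, 5, 10, 15, 60])
        f = np.append(np.exp(-0.1 * t[:4]), 0.0)
        fit = fit_inactivation(DecayTimeCourse(T=343.0, t=t, residual_fraction=f))
        assert fit.n_points_excluded == 1
        assert fit.n_points_used == 4  # t=0 anchor kept, contributes nothing
        assert fit.kd == pytest.approx(0.1, rel=1e-10)

    def test_zero_intercept_slope_matches_analytic_formula(self):
        """The through-origin estimator equals Σ t·ln f / Σ t², and on
        origin-anchored data agrees with generic OLS whose intercept → 0."""
        rng = np.random.default_rng(5)
        t = np.linspace(2, 120, 10)
        f = np.exp(-0.02 * t) * (1 + 0.01 * rng.standard_normal(t.size))
        fit = fit_inactivation(DecayTimeCourse(T=323.0, t=t, residual_fraction=f))
        analytic = -np.sum(t * np.log(f)) / np.sum(t * t)
        assert fit.kd == pytest.approx(analytic, rel=1e-14)
        slope, intercept = np.polyfit(t, np.log(f), 1)
        free = fit_inactivation(
            DecayTimeCourse(T=323.0, t=t, residual_fraction=f), through_origin=False
        )
        assert free.kd == pytest.approx(-slope, rel=1e-12)
        assert abs(intercept) < 0.05

    def test_all_unusable_rejected(self):
        course = DecayTimeCourse(T=353.0, t=[5.0, 10.0], residual_fraction=[0.0, 0.0])
        with pytest.raises(ValueError):
            fit_inactivation(course)

    def test_growing_activity_rejected(self):
        course = DecayTimeCourse(T=313.0, t=[5.0, 10.0], residual_fraction=[1.02, 1.05])
        with pytest.raises(ValueError, match="did not decay"):
            fit_inactivation(course)


class TestDerivedTimes:
    @pytest.mark.parametrize(
        "kd, expected_half_life",
        [(2.0e-4, 3466), (2.2e-3, 315), (2.8e-2, 25)],
    )
    def test_published_half_lives(self, kd, expected_half_life):
        assert round(half_life(kd)) == expected_half_life

    def test_published_decimal_reduction(self):
        assert round(decimal_reduction(2.2e-3)) == 1047

    def test_unit_rates(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)
        assert decimal_reduction(math.log(10)) == pytest.approx(1.0)

    @given(st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=50, derandomize=True)
    def test_ratio_identity(self, kd):
        """D/t½ = ln10/ln2 for every positive kd."""
        assert decimal_reduction(kd) / half_life(kd) == pytest.approx(
            LN10_OVER_LN2, rel=1e-14
        )

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)
        with pytest.raises(ValueError):
            decimal_reduction(-1.0)


class TestDeactivationEnergy:
    def test_published_panel_regression(self, kd_panel_fits):
        """OLS over the published five (T, kd) pairs gives ≈195 kJ/mol."""
        fit = deactivation_energy(kd_panel_fits)
        assert fit.Ea / 1e3 == pytest.approx(195.4, rel=0.01)

    def test_two_point_exact(self, kd_panel_fits):
        T = np.array([313.0, 353.0])
        kds = np.exp(30.0 - 100000.0 / (R * T))
        fits = [
            type(kd_panel_fits[0])(
                T=t, kd=k, half_life=half_life(k), D_value=decimal_reduction(k),
                r_squared=1.0, n_points_used=0,
            )
            for t, k in zip(T, kds)
        ]
        assert deactivation_energy(fits).Ea == pytest.approx(100000.0, rel=1e-10)

    def test_constant_kd_gives_zero(self, kd_panel_fits):
        fits = [f for f in kd_panel_fits[:2]]
        for f in fits:
            f.kd = 1e-3
        assert deactivation_energy(fits).Ea == 0.0

    def test_single_temperature_rejected(self, kd_panel_fits):
        with pytest.raises(ValueError):
            deactivation_energy(kd_panel_fits[:1])


class TestDeactivationParams:
    def test_published_row_313K(self, kd_panel_fits):
        row = deactivation_params(195.4e3, kd_panel_fits[0])
        assert round(row.dG_D / 1e3, 1) == 109.6
        assert round(row.dH_D / 1e3, 1) == 192.8
        assert round(row.dS_D, 1) == 265.8

    def test_published_row_333K(self, kd_panel_fits):
        row = deactivation_params(195.4e3, kd_panel_fits[2])
        assert round(row.dG_D / 1e3, 1) == 103.1

    def test_ea_equal_rt_gives_zero_enthalpy(self, kd_panel_fits):
        T = kd_panel_fits[0].T
        row = deactivation_params(R * T, kd_panel_fits[0])
        assert row.dH_D == pytest.approx(0.0, abs=1e-9)

    def test_gibbs_identity_on_every_row(self, kd_panel_fits):
        table = deactivation_table(kd_panel_fits)
        for row in table.per_T:
            assert row.dG_D == pytest.approx(row.dH_D - row.T * row.dS_D, abs=30)

    def test_monotone_ordering_across_panel(self, kd_panel_fits):
        """kd increasing with T forces t½ and D strictly decreasing."""
        fits = sorted(kd_panel_fits, key=lambda f: f.T)
        kds = [f.kd for f in fits]
        assert all(a < b for a, b in zip(kds, kds[1:]))
        hl = [f.half_life for f in fits]
        dv = [f.D_value for f in fits]
        assert all(a > b for a, b in zip(hl, hl[1:]))
        assert all(a > b for a, b in zip(dv, dv[1:]))


class TestBondsBroken:
    def test_published_estimate(self):
        assert bonds_broken(192.8e3) == pytest.approx(35.7, abs=0.05)

    @pytest.mark.parametrize("dh, expected", [(0.0, 0.0), (5400.0, 1.0)])
    def test_boundary_values(self, dh, expected):
        assert bonds_broken(dh) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bonds_broken(-1.0)
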