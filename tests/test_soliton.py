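"""Nonlinear capacitance, log-volume law, Toda-lattice soliton."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import windkessel5 as wk

DEFAULT = wk.TodaParams()  # a = -1, b = -1, L1 = 1 (exact lattice point)


class TestCapacitanceLaw:
    def test_reference_point(self):
        assert wk.pressure_dependent_capacitance(0.0, DEFAULT) == pytest.approx(1.0)

    def test_positive_over_operating_range(self):
        P = np.linspace(0.0, 200.0, 100)
        C = wk.pressure_dependent_capacitance(P, DEFAULT)
        assert np.all(C > 0)

    def test_singular_pressure_rejected(self):
        params = wk.TodaParams(a=-1.0, b=-1.0)
        with pytest.raises(wk.ParameterError, match="singular"):
            wk.pressure_dependent_capacitance(-1.0, params)  # aP + b = 0

    def test_zero_slope_forbidden(self):
        with pytest.raises(wk.ParameterError):
            wk.TodaParams(a=0.0, b=-1.0)

    def test_inconsistent_sign_forbidden(self):
        with pytest.raises(wk.ParameterError):
            wk.TodaParams(a=-1.0, b=1.0)  # b/a < 0: log argument flips sign


class TestVolumeLaw:
    def test_zero_pressure_zero_volume(self):
        assert wk.toda_volume(0.0, DEFAULT) == 0.0

    def test_closed_form_point(self):
        # a = b = -1: Q1(e - 1) = log(e) = 1
        assert wk.toda_volume(math.e - 1.0, DEFAULT) == pytest.approx(1.0, rel=1e-12)

    def test_domain_violation_rejected(self):
        with pytest.raises(wk.ParameterError, match="positive"):
            wk.toda_volume(-1.5, DEFAULT)  # (a/b) P1 + 1 = -0.5

    @pytest.mark.parametrize("P1", [0.5, 5.0, 50.0, 150.0])
    def test_equals_quadrature_of_capacitance(self, P1):
        """Q1(P1) is the integral of C1(P) dP from 0 to P1 (1e-8 relative)."""
        expected, _ = quad(
            lambda p: wk.pressure_dependent_capacitance(p, DEFAULT), 0.0, P1
        )
        assert wk.toda_volume(P1, DEFAULT) == pytest.approx(expected, rel=1e-8)

    @given(P1=st.floats(min_value=0.01, max_value=100.0))
    def test_derivative_is_the_capacitance(self, P1):
        """Fundamental theorem: dQ1/dP1 = C1(P1), by central differences."""
        h = 1e-5 * max(1.0, P1)
        fd = (wk.toda_volume(P1 + h, DEFAULT) - wk.toda_volume(P1 - h, DEFAULT)) / (2 * h)
        assert fd == pytest.approx(
            wk.pressure_dependent_capacitance(P1, DEFAULT), rel=1e-6
        )


class TestOneSoliton:
    def test_amplitude_vanishes_with_kappa(self):
        t = np.linspace(0.0, 5.0, 100)
        V = wk.toda_one_soliton(1e-4, np.arange(-3, 4), t)
        assert np.max(np.abs(V)) < 1e-7  # sinh(kappa)^2 -> 0

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(wk.ParameterError):
            wk.toda_one_soliton(0.0, [0], [0.0])

    def test_lattice_equation_holds_analytically(self):
        """With the analytic second derivative the 1-soliton satisfies the
        lattice equation to machine precision (< 1e-6 comfortably)."""
        t = np.linspace(0.0, 5.0, 2001)
        res = wk.toda_lattice_residual(1.0, np.arange(-8, 9), t, method="analytic")
        assert np.max(np.abs(res)) < 1e-6

    def test_lattice_equation_holds_by_finite_differences(self):
        t = np.arange(0.0, 5.0, 1e-3)
        res = wk.toda_lattice_residual(1.0, np.arange(-5, 6), t, method="fd")
        assert np.max(np.abs(res)) < 5e-6  # O(dt^2) of the time stencil

    def test_travels_without_changing_shape(self):
        """Profile at t and t + delta coincide after shifting sites by
        speed * delta (real-valued shift; continuous profile)."""
        kappa = 1.0
        speed = math.sinh(kappa) / kappa  # sites per unit time
        sites = np.linspace(-6.0, 6.0, 241)
        delta = 0.7
        before = wk.toda_one_soliton(kappa, sites - speed * delta, [0.0])
        after = wk.toda_one_soliton(kappa, sites, [delta])
        assert np.max(np.abs(before - after)) < 1e-6

    @given(kappa=st.floats(min_value=0.05, max_value=3.0))
    def test_soliton_is_supersonic(self, kappa):
        assert math.sinh(kappa) / kappa > 1.0


class TestReducedEquation:
    def test_constant_pressures_give_zero_residual(self):
        n = 100
        p = np.full(n, 0.5)
        res = wk.eq6_residual(p, p, p, DEFAULT, dt=0.01)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            wk.eq6_residual(np.zeros(5), np.zeros(5), np.zeros(4), DEFAULT, 0.01)

    def test_log_domain_violation_names_node(self):
        p = np.zeros(10)
        bad = p.copy()
        bad[4] = -2.0  # (a/b) P1 + 1 <= 0 there
        with pytest.raises(wk.ParameterError, match="node 4"):
            wk.eq6_residual(p, bad, p, DEFAULT, 0.01)

    def test_soliton_triple_satisfies_reduced_equation(self):
        """A lattice 1-soliton mapped to (P0, P1, P2) solves the reduced
        pressure equation at its exact-correspondence point L1 = -b."""
        t = np.arange(-4.0, 4.0, 1e-3)
        P0, P1, P2 = wk.soliton_pressure_triple(1.0, 0, t, DEFAULT)
        res = wk.eq6_residual(P0, P1, P2, DEFAULT, dt=1e-3)
        assert np.max(np.abs(res)) < 5e-6

    def test_main_model_trajectory_residual_is_finite_but_nonzero(self):
        """The linear-capacitance circuit does not follow the nonlinear
        reduction; its residual is a reported diagnostic, not ~0."""
        traj, _ = wk.run_preset("fig6", grid=wk.SimulationGrid(dt=0.002, t_end=10.0))
        p = wk.PRESETS["fig6"]
        # rescale pressures into the (a/b) P1 + 1 > 0 window
        P0, P1, P2 = wk.main_model_triple(traj, p, convention="eq3")
        scale = 1e-3
        res = wk.eq6_residual(scale * P0, scale * P1, scale * P2, DEFAULT, traj.dt)
        assert np.all(np.isfinite(res))
        assert np.max(np.abs(res)) > 0

    def test_sign_convention_flag(self):
        traj, _ = wk.run_preset("fig6", grid=wk.SimulationGrid(dt=0.002, t_end=5.0))
        p = wk.PRESETS["fig6"]
        _, _, P2_eq3 = wk.main_model_triple(traj, p, convention="eq3")
        _, _, P2_eq1 = wk.main_model_triple(traj, p, convention="eq1")
        np.testing.assert_allclose(P2_eq3 + P2_eq1, 2.0 * traj.P1, rtol=1e-9)
        with pytest.raises(ValueError):
            wk.main_model_triple(traj, p, convention="eq2")


class TestReductionPrecondition:
    def test_equal_compliances_are_exactly_solitonic(self):
        p = wk.CircuitParams(C2=0.05, L1=10.0, L2=10.0)
        traj = wk.simulate(p, grid=wk.SimulationGrid(dt=0.002, t_end=10.0))
        diag = wk.reduction_precondition_check(traj, p)
        assert diag.mismatch_term_max == 0.0
        assert diag.solitonic_regime

    def test_still_daughter_is_solitonic(self, waveform):
        p = wk.CircuitParams(C2=0.001, L1=10.0, L2=0.0)
        traj = wk.simulate_degenerate_L2_zero(
            p, waveform, wk.SimulationGrid(dt=0.002, t_end=5.0)
        )
        # F2 tracks F1/101: dF2/dt is tiny relative to the inertial term
        diag = wk.reduction_precondition_check(traj, p)
        assert diag.solitonic_regime

    def test_ordinary_scenario_reports_threshold_dependent_verdict(self):
        p = wk.CircuitParams(C2=0.08, L1=10.0, L2=5.0)
        traj = wk.simulate(p, grid=wk.SimulationGrid(dt=0.002, t_end=20.0))
        diag = wk.reduction_precondition_check(traj, p)
        assert diag.ratio > 0
        strict = wk.reduction_precondition_check(traj, p, threshold=1e-12)
        assert not strict.solitonic_regime
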