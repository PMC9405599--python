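"""Circuit relations: drive evaluation, branch flow, pressure recovery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import windkessel5 as wk


class TestDrive:
    @pytest.mark.parametrize(
        "t_factor, expected",
        [
            (0.0, (50.0, 100.0)),  # mean flow / pressure at t = 0
            (0.25, (60.0, 120.0)),  # sine peak: systolic values
            (0.75, (40.0, 80.0)),  # sine trough: diastolic values
        ],
    )
    def test_drive_hits_physiological_extremes(self, waveform, t_factor, expected):
        t = t_factor / waveform.frequency
        flow, pressure = wk.evaluate_drive(waveform, t)
        assert flow == pytest.approx(expected[0])
        assert pressure == pytest.approx(expected[1])

    def test_drive_is_periodic(self, waveform):
        t = np.linspace(0.0, 3.0, 301)
        f0, p0 = wk.evaluate_drive(waveform, t)
        f1, p1 = wk.evaluate_drive(waveform, t + 1.0 / waveform.frequency)
        np.testing.assert_allclose(f0, f1, atol=1e-9)
        np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(wk.ParameterError):
            wk.DrivingWaveform(frequency=0.0)
        with pytest.raises(wk.ParameterError):
            wk.DrivingWaveform(flow_offset=math.inf)

    def test_analytic_derivatives_match_finite_differences(self, waveform):
        t = np.linspace(0.1, 2.0, 50)
        h = 1e-6
        fd1 = (waveform.flow(t + h) - waveform.flow(t - h)) / (2 * h)
        np.testing.assert_allclose(waveform.flow_deriv(t, 1), fd1, rtol=1e-7, atol=1e-6)
        fd2 = (waveform.pressure(t + h) - 2 * waveform.pressure(t)
               + waveform.pressure(t - h)) / h**2
        np.testing.assert_allclose(waveform.pressure_deriv(t, 2), fd2, rtol=1e-3)


class TestBranchFlow:
    def test_printed_operating_point(self):
        # F = 50, P = 100, R = 2.2 -> F1 = 50 - 100/2.2
        assert wk.branch_flow(50.0, 100.0, 2.2) == pytest.approx(4.5455, abs=1e-4)

    def test_zero_pressure_diverts_everything(self):
        assert wk.branch_flow(37.0, 0.0, 2.2) == pytest.approx(37.0)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(wk.ParameterError):
            wk.branch_flow(50.0, 100.0, 0.0)

    def test_diversion_ratio_is_constant_one_eleventh(self, waveform):
        # P(t) = 2 F(t) numerically, so F1/F = 1 - 2/R = 1/11 at every t
        t = np.linspace(0.0, 5.0, 1000)
        F, P = wk.evaluate_drive(waveform, t)
        ratio = wk.branch_flow(F, P, 2.2) / F
        np.testing.assert_allclose(ratio, 1.0 / 11.0, rtol=1e-12)


class TestPressureRecovery:
    def test_zero_inductance_passes_pressure_through(self, waveform, dense_t):
        P = waveform.pressure(dense_t)
        d = np.zeros_like(dense_t)
        np.testing.assert_array_equal(wk.mother_pressure(P, d, 0.0), P)
        np.testing.assert_array_equal(wk.daughter_pressure(P, d, 0.0), P)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            wk.mother_pressure(np.zeros(5), np.zeros(4), 10.0)
        with pytest.raises(ValueError, match="misaligned"):
            wk.daughter_pressure(np.zeros(3), np.zeros(7), 10.0)

    def test_mother_pressure_peak_and_start(self, waveform, dense_t):
        # two-phase sinusoid: max P1 = 100 + sqrt(400 + (100 w / 11)^2)
        w = waveform.omega
        P = waveform.pressure(dense_t)
        dF1 = waveform.flow_deriv(dense_t, 1) - waveform.pressure_deriv(dense_t, 1) / 2.2
        P1 = wk.mother_pressure(P, dF1, 10.0)
        expected_max = 100.0 + math.sqrt(400.0 + (100.0 * w / 11.0) ** 2)
        assert np.max(P1) == pytest.approx(expected_max, rel=1e-6)
        assert P1[0] == pytest.approx(100.0 - 10.0 * (10.0 / 11.0) * w, rel=1e-9)
        assert P1[0] == pytest.approx(33.36, abs=0.01)

    def test_still_daughter_inherits_mother_pressure(self, waveform, dense_t):
        P1 = waveform.pressure(dense_t)
        np.testing.assert_array_equal(
            wk.daughter_pressure(P1, np.zeros_like(dense_t), 20.0), P1
        )


class TestOscillatorForcing:
    def test_constant_drive_gives_zero_forcing(self):
        quiet = wk.DrivingWaveform(flow_amplitude=0.0, pressure_amplitude=0.0)
        t = np.linspace(0.0, 10.0, 100)
        np.testing.assert_allclose(
            wk.rhs_eq2(t, wk.CircuitParams(), quiet), 0.0, atol=1e-14
        )

    def test_forcing_at_time_zero_is_omega(self, waveform):
        # at t = 0 the flow/pressure curvatures vanish: rhs(0) = 20 w / L2 = w
        params = wk.CircuitParams(L1=10.0, L2=20.0)
        assert wk.rhs_eq2(0.0, params, waveform) == pytest.approx(
            waveform.omega, rel=1e-12
        )
        assert wk.rhs_eq2(0.0, params, waveform) == pytest.approx(7.330, abs=1e-3)

    def test_forcing_is_heartbeat_periodic(self, waveform):
        params = wk.CircuitParams()
        t = np.linspace(0.0, 2.0, 500)
        np.testing.assert_allclose(
            wk.rhs_eq2(t, params, waveform),
            wk.rhs_eq2(t + 1.0 / waveform.frequency, params, waveform),
            atol=1e-9,
        )

    def test_degenerate_parameters_direct_to_other_branch(self, waveform):
        with pytest.raises(wk.DegenerateParameterError, match="L2 = 0"):
            wk.rhs_eq2(0.0, wk.CircuitParams(L2=0.0), waveform)
        with pytest.raises(wk.DegenerateParameterError):
            wk.rhs_eq2(0.0, wk.CircuitParams(C2=0.0), waveform)


class TestCircuitParams:
    @pytest.mark.parametrize(
        "kwargs", [{"R": -1.0}, {"R": 0.0}, {"C1": 0.0}, {"C2": -0.1}, {"L1": -5.0}]
    )
    def test_domain_violations_rejected(self, kwargs):
        with pytest.raises(wk.ParameterError):
            wk.CircuitParams(**kwargs)

    def test_natural_frequency(self):
        p = wk.CircuitParams(C2=0.005, L2=20.0)
        assert p.natural_omega == pytest.approx(1.0 / math.sqrt(0.1))
        with pytest.raises(wk.DegenerateParameterError):
            wk.CircuitParams(L2=0.0).natural_omega


class TestLinearity:
    @given(scale=st.floats(min_value=0.1, max_value=5.0))
    def test_doubling_drive_amplitudes_scales_zero_mean_parts(self, scale):
        """All recovered series are linear in the drive amplitudes: scaling
        both amplitudes (offsets fixed) scales the zero-mean parts."""
        base = wk.DrivingWaveform()
        scaled = wk.DrivingWaveform(
            flow_amplitude=scale * base.flow_amplitude,
            pressure_amplitude=scale * base.pressure_amplitude,
        )
        params = wk.PRESETS["fig3_caption"]
        grid = wk.SimulationGrid(dt=0.002, t_end=5.0)
        # zero initial state so the homogeneous tone scales with the drive
        quiet_init = wk.InitialState(F2_0=0.0, dF2dt_0=0.0)
        a = wk.simulate(params, base, quiet_init, grid)
        b = wk.simulate(params, scaled, quiet_init, grid)
        for name in ("F1", "F2"):
            sa, sb = getattr(a, name), getattr(b, name)
            np.testing.assert_allclose(sb - sb.mean(), scale * (sa - sa.mean()),
                                       atol=1e-8 * max(1.0, scale))
        for name in ("P1", "P2"):
            sa, sb = getattr(a, name), getattr(b, name)
            np.testing.assert_allclose(sb - sb.mean(), scale * (sa - sa.mean()),
                                       atol=1e-7 * max(1.0, scale))
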