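"""Circuit relations of the five-element Windkessel aneurysm model.

The two-story (mother + daughter) intracranial aneurysm is modelled as an
RLC analogue hanging off a parent artery whose flow F(t) and pressure P(t)
are prescribed by the heartbeat:

    R (F - F1)              = P          (neck resistance)
    Q1/C1 + L1 dF1/dt       = P          (mother sac)
    Q2/C2 + L2 dF2/dt       = Q1/C1      (daughter sac)

with Q_i = C_i * P_i the stored blood volume and P_i the local pressure on
each compliance.  Electrical symbols I, I1, I2, V are pure aliases of
F, F1, F2, P.  Eliminating everything but the daughter flow yields a driven
harmonic oscillator,

    F2'' + F2 / (C2 L2) = d/dt [ P/L2 - (L1/L2) d/dt (F - P/R) ],

whose forcing is evaluated analytically here (the drive is a known
sinusoid; differencing it numerically would only inject discretization
noise into the right-hand side).

Units follow the source convention: pressures in mmHg, flows in mL/min,
time in seconds, R/C/L as printed, derivatives per second.  The model is an
analogue and is not dimensionally closed; all numbers are used as printed.
Flows and pressures may be negative (the intra-aneurysmal flow direction
alternates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateParameterError, ParameterError

__all__ = [
    "DrivingWaveform",
    "CircuitParams",
    "InitialState",
    "Trajectory",
    "evaluate_drive",
    "branch_flow",
    "mother_pressure",
    "daughter_pressure",
    "rhs_eq2",
    "kirchhoff_residuals",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class DrivingWaveform:
    """Sinusoidal parent-artery source: F(t) = A_F sin(2*pi*f*t) + F(0),
    P(t) = A_P sin(2*pi*f*t) + P(0).

    Defaults are the physiological reference point: mean middle-cerebral
    flow 50 mL/min swinging 40-60, pressure 100 mmHg swinging 80-120, and a
    70 bpm heartbeat (f = 70/60 1/s).
    """

    flow_offset: float = 50.0
    flow_amplitude: float = 10.0
    pressure_offset: float = 100.0
    pressure_amplitude: float = 20.0
    frequency: float = 70.0 / 60.0

    def __post_init__(self) -> None:
        for name in ("flow_offset", "flow_amplitude", "pressure_offset",
                     "pressure_amplitude", "frequency"):
            _require_finite(name, getattr(self, name))
        if self.frequency <= 0:
            raise ParameterError(f"frequency must be > 0, got {self.frequency}")

    @property
    def omega(self) -> float:
        """Drive angular frequency 2*pi*f [rad/s]."""
        return 2.0 * math.pi * self.frequency

    def flow(self, t):
        return self.flow_amplitude * np.sin(self.omega * t) + self.flow_offset

    def pressure(self, t):
        return self.pressure_amplitude * np.sin(self.omega * t) + self.pressure_offset

    def flow_deriv(self, t, order: int = 1):
        """Analytic d^order F/dt^order for order in {1, 2}."""
        w = self.omega
        if order == 1:
            return self.flow_amplitude * w * np.cos(w * t)
        if order == 2:
            return -self.flow_amplitude * w * w * np.sin(w * t)
        raise ValueError(f"order must be 1 or 2, got {order}")

    def pressure_deriv(self, t, order: int = 1):
        """Analytic d^order P/dt^order for order in {1, 2}."""
        w = self.omega
        if order == 1:
            return self.pressure_amplitude * w * np.cos(w * t)
        if order == 2:
            return -self.pressure_amplitude * w * w * np.sin(w * t)
        raise ValueError(f"order must be 1 or 2, got {order}")


@dataclass(frozen=True)
class CircuitParams:
    """The five lumped elements.

    R   neck resistance (large R blocks flow into the sac),
    C1  mother-sac capacitance (sac size/volume per unit pressure),
    C2  daughter-sac capacitance,
    L1  mother compliance inductance (wall elasticity / thinness),
    L2  daughter compliance inductance.

    Defaults are the reference dumbbell setting R = 2.2, C1 = 0.100,
    C2 = 0.005, L1 = 10, L2 = 20 (the ``fig3_caption`` preset).
    """

    R: float = 2.2
    C1: float = 0.100
    C2: float = 0.005
    L1: float = 10.0
    L2: float = 20.0

    def __post_init__(self) -> None:
        for name in ("R", "C1", "C2", "L1", "L2"):
            _require_finite(name, getattr(self, name))
        if self.R <= 0:
            raise ParameterError(f"R must be > 0, got {self.R}")
        if self.C1 <= 0:
            raise ParameterError(f"C1 must be > 0, got {self.C1}")
        for name in ("C2", "L1", "L2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def size_ratio(self) -> float:
        """Daughter-to-mother size ratio C2/C1."""
        return self.C2 / self.C1

    @property
    def is_degenerate(self) -> bool:
        """True when the oscillator stiffness 1/(C2*L2) is undefined."""
        return self.C2 * self.L2 == 0.0

    @property
    def natural_omega(self) -> float:
        """Natural angular frequency omega0 = 1/sqrt(C2*L2) [rad/s]."""
        if self.is_degenerate:
            raise DegenerateParameterError(
                "omega0 = 1/sqrt(C2*L2) is undefined for C2*L2 = 0; "
                "use the degenerate L2 = 0 branch"
            )
        return 1.0 / math.sqrt(self.C2 * self.L2)


@dataclass(frozen=True)
class InitialState:
    """Initial daughter flow and its rate: F2(0) = 0.58 mL/min, dF2/dt(0) = 0."""

    F2_0: float = 0.58
    dF2dt_0: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("F2_0", self.F2_0)
        _require_finite("dF2dt_0", self.dF2dt_0)


@dataclass(frozen=True)
class Trajectory:
    """Time-gridded series of every model quantity on one uniform grid.

    Satisfies pointwise: F1 = F - P/R, Q1 = C1*P1, Q2 = C2*P2.
    """

    t: np.ndarray
    F: np.ndarray
    P: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    Q1: np.ndarray
    Q2: np.ndarray

    _SERIES = ("F", "P", "F1", "F2", "P1", "P2", "Q1", "Q2")

    def __post_init__(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise ValueError("trajectory needs at least two nodes")
        for name in self._SERIES:
            arr = getattr(self, name)
            if arr.shape != self.t.shape:
                raise ValueError(
                    f"series {name} has shape {arr.shape}, grid has {self.t.shape}"
                )
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid is not uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return int(self.t.shape[0])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, **{k: getattr(self, k) for k in self._SERIES}}
        )

    def __eq__(self, other) -> bool:  # bit-exact comparison, used by I/O round-trips
        if not isinstance(other, Trajectory):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, k), getattr(other, k))
            for k in ("t",) + self._SERIES
        )


def evaluate_drive(waveform: DrivingWaveform, t):
    """Parent-artery (flow, pressure) at time(s) ``t``.

    Defaults give (50, 100) at t = 0 and peak at (60, 120).
    """
    return waveform.flow(t), waveform.pressure(t)


def branch_flow(F, P, R: float):
    """Flow diverted into the mother sac, F1 = F - P/R (neck relation).

    May be negative: the intra-aneurysmal flow direction alternates.
    """
    if R <= 0:
        raise ParameterError(f"R must be > 0, got {R}")
    out = np.asarray(F, dtype=float) - np.asarray(P, dtype=float) / R
    return out if out.ndim else float(out)


def _check_aligned(a, b, what: str) -> None:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"misaligned series in {what}: {a.shape} vs {b.shape}")


def mother_pressure(P, dF1dt, L1: float):
    """Mother-sac pressure P1 = P - L1 * dF1/dt.

    ``dF1dt`` should come analytically from the sinusoidal drive
    (``waveform.flow_deriv`` minus ``waveform.pressure_deriv``/R).
    """
    _check_aligned(P, dF1dt, "mother_pressure")
    return np.asarray(P) - L1 * np.asarray(dF1dt)


def daughter_pressure(P1, dF2dt, L2: float):
    """Daughter-sac pressure P2 = P1 - L2 * dF2/dt.

    Algebraic in P1 and dF2/dt; no initial volume Q2(0) is needed.
    """
    _check_aligned(P1, dF2dt, "daughter_pressure")
    return np.asarray(P1) - L2 * np.asarray(dF2dt)


def rhs_eq2(t, params: CircuitParams, waveform: DrivingWaveform):
    """Forcing of the daughter-flow oscillator,
    P'(t)/L2 - (L1/L2) * (F''(t) - P''(t)/R),
    with all drive derivatives taken in closed form.
    """
    if params.L2 == 0 or params.C2 == 0:
        raise DegenerateParameterError(
            "the oscillator forcing is undefined for C2*L2 = 0; "
            "use simulate_degenerate_L2_zero for the L2 = 0 branch"
        )
    L1, L2, R = params.L1, params.L2, params.R
    return waveform.pressure_deriv(t, 1) / L2 - (L1 / L2) * (
        waveform.flow_deriv(t, 2) - waveform.pressure_deriv(t, 2) / R
    )


def kirchhoff_residuals(traj: Trajectory, params: CircuitParams):
    """Charge-balance residual series at the two storage nodes.

    Returns ``(res1, res2)`` evaluated at the interior grid nodes by
    central differences:

        res1 = d(C1*P1)/dt - (F1 - F2)     (mother node)
        res2 = d(C2*P2)/dt -  F2           (daughter node)

    The daughter balance is built into the oscillator equation and its
    residual shrinks as O(dt^2).  The mother balance is *not* enforced by
    the model: once F(t) and P(t) are both prescribed, F1 is fixed by the
    neck relation and P1 by the mother relation, leaving dQ1/dt = F1 - F2
    structurally violated (res1 is O(1) regardless of dt).  Both series are
    returned as diagnostics of this asymmetry.

    The first and last interior nodes are dropped: there P2 (hence Q2)
    rests on the one-sided dF2/dt boundary stencil, whose error converges
    one order slower and would mask the interior O(dt^2) behaviour.
    """
    dt = traj.dt
    dQ1 = (traj.Q1[3:-1] - traj.Q1[1:-3]) / (2.0 * dt)
    dQ2 = (traj.Q2[3:-1] - traj.Q2[1:-3]) / (2.0 * dt)
    res1 = dQ1 - (traj.F1[2:-2] - traj.F2[2:-2])
    res2 = dQ2 - traj.F2[2:-2]
    return res1, res2
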