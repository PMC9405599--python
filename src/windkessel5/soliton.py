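"""Solitonic reduction: pressure-dependent capacitance, log-volume law,
and the Toda-lattice correspondence.

When the mother compliance is pressure-softening, C1(P) = -(aP + b)^(-1),
the stored volume follows a logarithmic law

    Q1(P1) = -(1/a) * log((a/b) P1 + 1)            (integral of C1 dP)

and, provided L1 ~ L2 or dF2/dt ~ 0 so the compliance-mismatch term drops
out of the node balance, the pressure triple (P0, P1, P2) — the pressures
on the neck resistance, mother and daughter — obeys

    (L1/a) d^2/dt^2 log((a/b) P1 + 1) = 2 P1 - P2 - P0,

which is exactly one site of the Toda lattice written in its interaction
variables,

    d^2/dt^2 log(1 + V_n) = V_{n+1} + V_{n-1} - 2 V_n,

under P_{0,1,2} = (b/a) V_{n-1,n,n+1} and L1 = -b.  The lattice admits the
textbook 1-soliton

    V_n(t) = sinh(kappa)^2 * sech(kappa*n - sinh(kappa)*t)^2,

a compression pulse travelling at speed sinh(kappa)/kappa (> 1, i.e.
supersonic on the lattice) without change of shape.  The identity
1 + sinh(k)^2 sech(x)^2 = cosh(x+k) cosh(x-k) / cosh(x)^2 makes the
solution satisfy the lattice equation *identically*:
d^2/dt^2 log(1+V_n) = sinh(k)^2 [sech^2(x+k) + sech^2(x-k) - 2 sech^2(x)].

Constants a and b are never fixed by the physiology; defaults a = -1,
b = -1 give C1(0) = 1 > 0 over the physiological pressure range and put
the exact-correspondence point at L1 = -b = 1.

Sign convention: the reduction's node relations are taken as written
there, P2 - P1 = L2 dF2/dt and P1 - P0 = L1 dF1/dt ("eq3"), which is the
opposite L2 sign from the main circuit recovery P2 = P1 - L2 dF2/dt
("eq1").  Both are in the source; :func:`main_model_triple` carries an
explicit ``convention`` flag and defaults to "eq3".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import CircuitParams, Trajectory

__all__ = [
    "TodaParams",
    "ReductionDiagnostic",
    "pressure_dependent_capacitance",
    "toda_volume",
    "eq6_residual",
    "toda_one_soliton",
    "toda_log_second_derivative",
    "toda_lattice_residual",
    "soliton_pressure_triple",
    "main_model_triple",
    "reduction_precondition_check",
]


@dataclass(frozen=True)
class TodaParams:
    """Capacitance law C1(P) = -(aP + b)^(-1) plus the mother inductance.

    Requires a != 0 and b/a > 0 (so the log-volume argument is 1 at zero
    pressure).  The default L1 = -b = 1 is the exact Toda-correspondence
    point; the main model's L1 may be passed instead when diagnosing real
    trajectories.
    """

    a: float = -1.0
    b: float = -1.0
    L1: float = 1.0

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ParameterError("capacitance-law slope a must be nonzero")
        if self.b / self.a <= 0:
            raise ParameterError(
                f"b/a must be > 0 so that C1 is regular at P = 0, got {self.b / self.a}"
            )


def pressure_dependent_capacitance(P, params: TodaParams):
    """C1(P) = -1/(aP + b); positive wherever aP + b < 0."""
    denom = params.a * np.asarray(P, dtype=float) + params.b
    if np.any(denom == 0):
        raise ParameterError(
            f"singular capacitance: aP + b = 0 at P = {-params.b / params.a}"
        )
    out = -1.0 / denom
    return out if out.ndim else float(out)


def toda_volume(P1, params: TodaParams):
    """Stored volume Q1(P1) = -(1/a) log((a/b) P1 + 1).

    Equals the quadrature of the pressure-dependent capacitance from 0 to
    P1; Q1(0) = 0.
    """
    arg = (params.a / params.b) * np.asarray(P1, dtype=float) + 1.0
    if np.any(arg <= 0):
        raise ParameterError(
            "log-volume argument (a/b) P1 + 1 must be positive; "
            f"minimum was {float(np.min(arg)):g}"
        )
    out = -(1.0 / params.a) * np.log(arg)
    return out if out.ndim else float(out)


def eq6_residual(P0, P1, P2, params: TodaParams, dt: float) -> np.ndarray:
    """Residual of the reduced soliton equation on aligned pressure series.

    Returns (L1/a) d^2/dt^2 log((a/b) P1 + 1) - (2 P1 - P2 - P0) at the
    interior nodes (length n - 2), the second derivative taken by central
    differences.  Raises on misaligned series or a non-positive log
    argument (the error names the first offending node).
    """
    P0 = np.asarray(P0, dtype=float)
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    if not (P0.shape == P1.shape == P2.shape):
        raise ValueError(
            f"misaligned series: {P0.shape}, {P1.shape}, {P2.shape}"
        )
    arg = (params.a / params.b) * P1 + 1.0
    bad = np.flatnonzero(arg <= 0)
    if bad.size:
        raise ParameterError(
            f"log-volume argument <= 0 first at node {int(bad[0])}"
        )
    u = np.log(arg)
    d2u = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / (dt * dt)
    drive = 2.0 * P1 - P2 - P0
    return (params.L1 / params.a) * d2u - drive[1:-1]


def toda_one_soliton(kappa: float, sites, t_grid) -> np.ndarray:
    """1-soliton interaction variable V_n(t) on the given lattice sites.

    Returns an array of shape (len(sites), len(t_grid)) with
    V_n(t) = sinh(kappa)^2 sech(kappa*n - sinh(kappa)*t)^2.  Sites may be
    real (the profile is a continuous travelling wave sampled on the
    lattice).  Amplitude sinh(kappa)^2 -> 0 as kappa -> 0+.
    """
    if kappa <= 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    sites = np.atleast_1d(np.asarray(sites, dtype=float))
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    theta = kappa * sites[:, None] - math.sinh(kappa) * t[None, :]
    return math.sinh(kappa) ** 2 / np.cosh(theta) ** 2


def toda_log_second_derivative(kappa: float, sites, t_grid) -> np.ndarray:
    """Analytic d^2/dt^2 log(1 + V_n(t)) for the 1-soliton (oracle).

    Via 1 + sinh(k)^2 sech(x)^2 = cosh(x+k) cosh(x-k) / cosh(x)^2:
    the result is sinh(k)^2 [sech^2(x+k) + sech^2(x-k) - 2 sech^2(x)].
    """
    if kappa <= 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    sites = np.atleast_1d(np.asarray(sites, dtype=float))
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    theta = kappa * sites[:, None] - math.sinh(kappa) * t[None, :]
    s2 = math.sinh(kappa) ** 2
    sech2 = lambda x: 1.0 / np.cosh(x) ** 2
    return s2 * (sech2(theta + kappa) + sech2(theta - kappa) - 2.0 * sech2(theta))


def toda_lattice_residual(
    kappa: float, sites, t_grid, method: str = "analytic"
) -> np.ndarray:
    """Residual d^2/dt^2 log(1+V_n) - (V_{n+1} + V_{n-1} - 2 V_n) at the
    given interior sites.

    ``method="analytic"`` uses the closed-form second derivative (residual
    at machine precision); ``method="fd"`` uses central differences in time
    on the grid (residual O(dt^2)) and returns interior time nodes only.
    """
    sites = np.atleast_1d(np.asarray(sites, dtype=float))
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    V_dn = toda_one_soliton(kappa, sites - 1.0, t)
    V = toda_one_soliton(kappa, sites, t)
    V_up = toda_one_soliton(kappa, sites + 1.0, t)
    coupling = V_up + V_dn - 2.0 * V
    if method == "analytic":
        return toda_log_second_derivative(kappa, sites, t) - coupling
    if method == "fd":
        dt = float(t[1] - t[0])
        u = np.log1p(V)
        d2u = (u[:, 2:] - 2.0 * u[:, 1:-1] + u[:, :-2]) / (dt * dt)
        return d2u - coupling[:, 1:-1]
    raise ValueError(f"method must be 'analytic' or 'fd', got {method!r}")


def soliton_pressure_triple(
    kappa: float, site: int, t_grid, params: TodaParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P0, P1, P2) pressure series from a lattice 1-soliton.

    Maps neighbor sites (n-1, n, n+1) to (P0, P1, P2) via P = (b/a) V.
    With params.L1 = -params.b the triple satisfies the reduced equation
    exactly.
    """
    scale = params.b / params.a
    V = toda_one_soliton(kappa, [site - 1, site, site + 1], t_grid)
    return scale * V[0], scale * V[1], scale * V[2]


def main_model_triple(
    traj: Trajectory, params: CircuitParams, convention: str = "eq3"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P0, P1, P2) extracted from a circuit trajectory.

    P0 (pressure on the neck resistance) is P1 - L1 dF1/dt; P2 follows the
    selected L2 sign convention: "eq3" (reduction, P2 = P1 + L2 dF2/dt) or
    "eq1" (main recovery, P2 = P1 - L2 dF2/dt, i.e. the trajectory's own
    P2).  Derivatives by second-order finite differences.
    """
    dt = traj.dt
    dF1 = np.gradient(traj.F1, dt, edge_order=2)
    dF2 = np.gradient(traj.F2, dt, edge_order=2)
    P0 = traj.P1 - params.L1 * dF1
    if convention == "eq3":
        P2 = traj.P1 + params.L2 * dF2
    elif convention == "eq1":
        P2 = traj.P1 - params.L2 * dF2
    else:
        raise ValueError(f"convention must be 'eq3' or 'eq1', got {convention!r}")
    return P0, traj.P1, P2


@dataclass(frozen=True)
class ReductionDiagnostic:
    """How negligible the compliance-mismatch term is for a trajectory."""

    mismatch_term_max: float  # max |(L2 - L1) dF2/dt|
    inertial_term_max: float  # max |L1 d^2 Q1/dt^2|
    ratio: float
    solitonic_regime: bool
    threshold: float


def reduction_precondition_check(
    traj: Trajectory, params: CircuitParams, threshold: float = 0.1
) -> ReductionDiagnostic:
    """Check whether L1 ~ L2 or dF2/dt ~ 0 holds along a trajectory.

    Compares max |(L2 - L1) dF2/dt| against max |L1 d^2 Q1/dt^2| (the term
    retained by the reduction); the verdict is True when the ratio is
    below ``threshold``.  L1 = L2 gives an exactly zero mismatch term.
    """
    dt = traj.dt
    if params.L1 == params.L2:
        mismatch = 0.0
    else:
        dF2 = np.gradient(traj.F2, dt, edge_order=2)
        mismatch = float(np.max(np.abs((params.L2 - params.L1) * dF2)))
    d2Q1 = (traj.Q1[2:] - 2.0 * traj.Q1[1:-1] + traj.Q1[:-2]) / (dt * dt)
    inertial = float(np.max(np.abs(params.L1 * d2Q1)))
    ratio = mismatch / inertial if inertial > 0 else (0.0 if mismatch == 0 else math.inf)
    return ReductionDiagnostic(
        mismatch_term_max=mismatch,
        inertial_term_max=inertial,
        ratio=ratio,
        solitonic_regime=ratio <= threshold,
        threshold=threshold,
    )
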