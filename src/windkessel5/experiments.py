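"""Systematic calculations: presets, parameter sweeps and beat analysis.

The named presets are the printed benchmark settings of the reference
simulations; ``fig3_caption``/``fig3_text`` are the two printed variants of
the typical-dumbbell daughter capacitance (0.005 vs 0.05 — both sources are
kept, caption being the default dialect), ``fig5`` the single-sac
compliance study and ``fig6`` the slow-flow/high-pressure regime.

Two growth scenarios are distinguished in the daughter-size sweep by how
the daughter compliance tracks the mother's:

* ``ordinary``  — L2 = L1/2 (interpretation "caption"; the alternative
  printed reading L2 = 2*L1 is selectable as interpretation "text"),
* ``solitonic`` — L2 = L1, the regime in which the nonlinear reduction of
  :mod:`windkessel5.soliton` applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateParameterError, ParameterError, ResonanceError
from .integrate import (
    SimulationGrid,
    closed_form_trajectory,
    simulate,
    simulate_degenerate_L2_zero,
    solve_closed_form,
)
from .model import CircuitParams, DrivingWaveform, InitialState, Trajectory

__all__ = [
    "PRESETS",
    "SummaryStats",
    "SweepResult",
    "ToneFit",
    "run_preset",
    "summarize",
    "beat_analysis",
    "sweep_daughter_size",
    "sweep_compliance",
]

#: Printed benchmark parameter sets.  ``default`` is an alias of
#: ``fig3_caption``.
PRESETS: dict[str, CircuitParams] = {
    "fig3_caption": CircuitParams(R=2.2, C1=0.100, C2=0.005, L1=10.0, L2=20.0),
    "fig3_text": CircuitParams(R=2.2, C1=0.100, C2=0.05, L1=10.0, L2=20.0),
    # single-sac compliance study; L1 = 40 is the compliance risk border
    "fig5": CircuitParams(R=2.2, C1=0.100, C2=0.001, L1=40.0, L2=0.0),
    "fig6": CircuitParams(R=2.2, C1=0.100, C2=0.100, L1=30.0, L2=60.0),
}
PRESETS["default"] = PRESETS["fig3_caption"]


@dataclass(frozen=True)
class SummaryStats:
    """Window summary of one run.

    Maxima are taken over the full simulated window starting at t = 0 (the
    initial state is part of the model, not a transient to be discarded).
    Tone fields are NaN for degenerate (L2 = 0) runs, where no natural
    frequency exists.
    """

    max_P1: float
    max_P2: float
    max_abs_F2: float
    flow_diversion_ratio: float
    natural_period: float = math.nan
    drive_tone_amplitude: float = math.nan
    natural_tone_amplitude: float = math.nan
    beat_period: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return {
            "max_P1": self.max_P1,
            "max_P2": self.max_P2,
            "max_abs_F2": self.max_abs_F2,
            "flow_diversion_ratio": self.flow_diversion_ratio,
            "natural_period": self.natural_period,
            "drive_tone_amplitude": self.drive_tone_amplitude,
            "natural_tone_amplitude": self.natural_tone_amplitude,
            "beat_period": self.beat_period,
        }


@dataclass(frozen=True)
class ToneFit:
    """Least-squares two-tone decomposition of the daughter flow."""

    drive_tone_amplitude: float
    natural_tone_amplitude: float
    natural_period: float
    beat_period: float
    fit_residual: float


@dataclass(frozen=True)
class SweepResult:
    """One parameter sweep: a strictly increasing grid plus per-point
    circuit parameters and summary statistics."""

    sweep_variable: str
    values: np.ndarray
    params: list[CircuitParams]
    stats: list[SummaryStats]
    scenario: str | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.params) or len(self.values) != len(self.stats):
            raise ValueError("sweep grid, params and stats must align")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("sweep grid must be strictly increasing")

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for v, p, s in zip(self.values, self.params, self.stats):
            row = {self.sweep_variable: v}
            if self.scenario is not None:
                row["scenario"] = self.scenario
            row.update({"R": p.R, "C1": p.C1, "C2": p.C2, "L1": p.L1, "L2": p.L2})
            row.update(s.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def max_over_runs(self, stat: str) -> float:
        return max(getattr(s, stat) for s in self.stats)

    def min_over_runs(self, stat: str) -> float:
        return min(getattr(s, stat) for s in self.stats)


def beat_analysis(
    traj: Trajectory,
    params: CircuitParams,
    waveform: DrivingWaveform,
    resonance_tol: float = 1e-6,
) -> ToneFit:
    """Fit F2(t) = c_s sin(wt) + c_c cos(wt) + n_s sin(w0 t) + n_c cos(w0 t).

    The simulated daughter flow is exactly a two-tone signal (heartbeat
    tone at omega, natural tone at omega0 = 1/sqrt(C2 L2)), so the fit
    residual is at discretization level.  The beat period 2*pi/|w - w0| is
    the slow envelope of their superposition.
    """
    w = waveform.omega
    w0 = params.natural_omega
    if abs(w - w0) < resonance_tol:
        raise ResonanceError(
            f"|omega - omega0| = {abs(w - w0):.3g} < {resonance_tol:g}: "
            "the two tones are indistinguishable at resonance"
        )
    t = traj.t
    design = np.column_stack(
        [np.sin(w * t), np.cos(w * t), np.sin(w0 * t), np.cos(w0 * t)]
    )
    coef, *_ = np.linalg.lstsq(design, traj.F2, rcond=None)
    resid = traj.F2 - design @ coef
    return ToneFit(
        drive_tone_amplitude=float(np.hypot(coef[0], coef[1])),
        natural_tone_amplitude=float(np.hypot(coef[2], coef[3])),
        natural_period=2.0 * math.pi / w0,
        beat_period=2.0 * math.pi / abs(w - w0),
        fit_residual=float(np.max(np.abs(resid))),
    )


def summarize(
    traj: Trajectory,
    params: CircuitParams,
    waveform: DrivingWaveform,
) -> SummaryStats:
    """Window maxima, flow-diversion ratio and (when defined) tone metrics."""
    base = {
        "max_P1": float(np.max(traj.P1)),
        "max_P2": float(np.max(traj.P2)),
        "max_abs_F2": float(np.max(np.abs(traj.F2))),
        "flow_diversion_ratio": float(np.max(np.abs(traj.F1 / traj.F))),
    }
    if not params.is_degenerate:
        try:
            fit = beat_analysis(traj, params, waveform)
        except ResonanceError:
            pass
        else:
            base.update(
                natural_period=fit.natural_period,
                drive_tone_amplitude=fit.drive_tone_amplitude,
                natural_tone_amplitude=fit.natural_tone_amplitude,
                beat_period=fit.beat_period,
            )
    return SummaryStats(**base)


def _run(params, waveform, init, grid) -> Trajectory:
    if params.L2 == 0:
        return simulate_degenerate_L2_zero(params, waveform, grid)
    return simulate(params, waveform, init, grid)


def run_preset(
    name: str,
    waveform: DrivingWaveform | None = None,
    init: InitialState | None = None,
    grid: SimulationGrid | None = None,
) -> tuple[Trajectory, SummaryStats]:
    """Simulate a named printed parameter set; deterministic."""
    if name not in PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; options: {sorted(PRESETS)}"
        )
    params = PRESETS[name]
    waveform = waveform or DrivingWaveform()
    traj = _run(params, waveform, init or InitialState(), grid or SimulationGrid())
    return traj, summarize(traj, params, waveform)


def _scenario_L2(scenario: str, L1: float, l_interpretation: str) -> float:
    if scenario == "solitonic":
        return L1
    if scenario == "ordinary":
        if l_interpretation == "caption":
            return L1 / 2.0
        if l_interpretation == "text":
            return 2.0 * L1
        raise ParameterError(
            f"unknown L interpretation {l_interpretation!r}; "
            "options: ['caption', 'text']"
        )
    raise ParameterError(
        f"unknown scenario {scenario!r}; options: ['ordinary', 'solitonic']"
    )


def sweep_daughter_size(
    C1: float = 0.10,
    ratios: np.ndarray | None = None,
    scenario: str = "ordinary",
    L1: float = 10.0,
    R: float = 2.2,
    l_interpretation: str = "caption",
    waveform: DrivingWaveform | None = None,
    init: InitialState | None = None,
    grid: SimulationGrid | None = None,
) -> SweepResult:
    """Grow the daughter sac: C2/C1 over ``ratios`` (default 0.20 ... 1.00).

    The scenario fixes the daughter compliance relative to L1 (ordinary:
    L2 = L1/2 under the default "caption" interpretation, L2 = 2*L1 under
    "text"; solitonic: L2 = L1).
    """
    if ratios is None:
        ratios = np.linspace(0.2, 1.0, 9)
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0) or np.any(ratios > 1):
        raise DegenerateParameterError(
            "size ratios must lie in (0, 1]: ratio 0 has no daughter oscillator"
        )
    if L1 <= 0:
        raise ParameterError(f"L1 must be > 0 in a size sweep, got {L1}")
    L2 = _scenario_L2(scenario, L1, l_interpretation)
    waveform = waveform or DrivingWaveform()
    init = init or InitialState()
    grid = grid or SimulationGrid()
    params_list, stats_list = [], []
    for r in ratios:
        p = CircuitParams(R=R, C1=C1, C2=r * C1, L1=L1, L2=L2)
        traj = _run(p, waveform, init, grid)
        params_list.append(p)
        stats_list.append(summarize(traj, p, waveform))
    return SweepResult(
        sweep_variable="size_ratio",
        values=ratios,
        params=params_list,
        stats=stats_list,
        scenario=scenario,
    )


def sweep_compliance(
    C1: float = 0.10,
    C2: float = 0.001,
    L1_grid: np.ndarray | None = None,
    L2: float = 0.0,
    R: float = 2.2,
    waveform: DrivingWaveform | None = None,
    init: InitialState | None = None,
    grid: SimulationGrid | None = None,
) -> SweepResult:
    """Thin the mother wall: sweep L1 with a vestigial daughter (L2 = 0).

    The default grid 0, 10, ..., 80 covers the asymptotically linear range
    of the peak mother pressure and the L1 > 40 risk border.
    """
    if L1_grid is None:
        L1_grid = np.arange(0.0, 81.0, 10.0)
    L1_grid = np.asarray(L1_grid, dtype=float)
    if L1_grid.size == 0:
        raise ParameterError("L1 grid must not be empty")
    waveform = waveform or DrivingWaveform()
    init = init or InitialState()
    grid = grid or SimulationGrid()
    params_list, stats_list = [], []
    for L1 in L1_grid:
        p = CircuitParams(R=R, C1=C1, C2=C2, L1=float(L1), L2=L2)
        traj = _run(p, waveform, init, grid)
        params_list.append(p)
        stats_list.append(summarize(traj, p, waveform))
    return SweepResult(
        sweep_variable="L1",
        values=L1_grid,
        params=params_list,
        stats=stats_list,
    )
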