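"""Serialization: CSV for time series and sweeps, JSON for summaries.

Floats are written in shortest-round-trip representation, so
``read_timeseries(write_timeseries(traj)) == traj`` bit-exactly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import SummaryStats, SweepResult
from .geometry import RiskReport
from .model import Trajectory

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_summary",
    "write_sweep",
    "write_risk_report",
]

_COLUMNS = ("t", "F", "P", "F1", "F2", "P1", "P2", "Q1", "Q2")


def write_timeseries(traj: Trajectory, path: str | Path) -> Path:
    """CSV with header t,F,P,F1,F2,P1,P2,Q1,Q2; one row per grid node."""
    path = Path(path)
    traj.to_dataframe().to_csv(path, index=False)
    return path


def read_timeseries(path: str | Path) -> Trajectory:
    """Companion reader; lossless for files written by write_timeseries."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"time-series file {path} lacks column(s) {missing}")
    return Trajectory(**{c: df[c].to_numpy(dtype=float) for c in _COLUMNS})


def _jsonable(value):
    if isinstance(value, float) and not math.isfinite(value):
        return None
    if isinstance(value, (np.floating, np.integer)):
        return _jsonable(value.item())
    return value


def _dump(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def write_summary(
    stats: SummaryStats, path: str | Path, config: dict | None = None
) -> Path:
    """JSON summary; NaN tone fields (degenerate runs) serialize as null."""
    path = Path(path)
    payload = {
        "summary": {k: _jsonable(v) for k, v in stats.to_dict().items()},
    }
    if config is not None:
        payload["config"] = config
    _dump(payload, path)
    return path


def write_sweep(
    sweep: SweepResult,
    csv_path: str | Path,
    json_path: str | Path | None = None,
    config: dict | None = None,
) -> Path:
    """Sweep as CSV (one row per grid point) plus optional JSON summary."""
    csv_path = Path(csv_path)
    df = sweep.to_dataframe()
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "sweep_variable": sweep.sweep_variable,
            "scenario": sweep.scenario,
            "n_points": len(sweep.values),
            "max_P1_over_runs": _jsonable(sweep.max_over_runs("max_P1")),
            "max_P2_over_runs": _jsonable(sweep.max_over_runs("max_P2")),
            "min_max_P2_over_runs": _jsonable(sweep.min_over_runs("max_P2")),
        }
        if config is not None:
            payload["config"] = config
        _dump(payload, Path(json_path))
    return csv_path


def write_risk_report(
    report: RiskReport, path: str | Path, config: dict | None = None
) -> Path:
    """Rupture checklist as JSON, one entry per checklist item."""
    path = Path(path)
    payload = {
        "checklist": {
            k: {kk: _jsonable(vv) for kk, vv in item.items()}
            for k, item in report.to_checklist().items()
        },
        "scenario_notes": report.scenario_notes,
        "any_flag": report.any_flag,
    }
    if config is not None:
        payload["config"] = config
    _dump(payload, path)
    return path
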