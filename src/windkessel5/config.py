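"""Flat key-value run configuration.

A run is fully described by a flat mapping (YAML file or inline overrides)
over the documented keys below; a ``preset`` key is applied first and any
explicit key then overrides it.  Unknown keys are rejected so typos fail
loudly.  The resolved configuration is echoed into every output artifact,
and re-running from that echo reproduces the artifact bit-exactly (the
model is deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .errors import ConfigError, ParameterError
from .experiments import PRESETS
from .integrate import SimulationGrid
from .model import CircuitParams, DrivingWaveform, InitialState

__all__ = ["RunConfig", "load_config", "CONFIG_KEYS"]

_CIRCUIT_KEYS = ("R", "C1", "C2", "L1", "L2")
_WAVEFORM_KEYS = (
    "flow_offset",
    "flow_amplitude",
    "pressure_offset",
    "pressure_amplitude",
    "frequency",
)
_INIT_KEYS = ("F2_0", "dF2dt_0")
_GRID_KEYS = ("dt", "t_end")
_SWITCH_KEYS = ("preset", "fig4_l_interpretation", "l2_sign_convention")

#: every key load_config accepts
CONFIG_KEYS = _CIRCUIT_KEYS + _WAVEFORM_KEYS + _INIT_KEYS + _GRID_KEYS + _SWITCH_KEYS


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    params: CircuitParams
    waveform: DrivingWaveform
    init: InitialState
    grid: SimulationGrid
    preset: str | None = None
    fig4_l_interpretation: str = "caption"
    l2_sign_convention: str = "eq3"

    def to_flat_dict(self) -> dict:
        """Flat mapping of every resolved value (echoed into outputs)."""
        out: dict = {}
        for k in _CIRCUIT_KEYS:
            out[k] = getattr(self.params, k)
        for k in _WAVEFORM_KEYS:
            out[k] = getattr(self.waveform, k)
        for k in _INIT_KEYS:
            out[k] = getattr(self.init, k)
        for k in _GRID_KEYS:
            out[k] = getattr(self.grid, k)
        out["preset"] = self.preset
        out["fig4_l_interpretation"] = self.fig4_l_interpretation
        out["l2_sign_convention"] = self.l2_sign_convention
        return out


def _coerce_number(key: str, value) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"key {key!r} needs a number, got {value!r}")
    return float(value)


def load_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> RunConfig:
    """Build a :class:`RunConfig` from a flat YAML file and/or overrides.

    Precedence: built-in defaults < preset < explicit file keys <
    ``overrides``.  An empty file (or no file) yields the full default
    setting (R = 2.2, f = 70/60, F(0) = 50, P(0) = 100, dt = 0.002, ...).
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a flat mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    unknown = sorted(set(data) - set(CONFIG_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {unknown}; known keys: {sorted(CONFIG_KEYS)}"
        )

    preset = data.get("preset")
    if preset is not None and preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    params = PRESETS[preset] if preset is not None else CircuitParams()

    circuit_overrides = {
        k: _coerce_number(k, data[k]) for k in _CIRCUIT_KEYS if k in data
    }
    try:
        if circuit_overrides:
            params = replace(params, **circuit_overrides)
        waveform = DrivingWaveform(
            **{k: _coerce_number(k, data[k]) for k in _WAVEFORM_KEYS if k in data}
        )
        init = InitialState(
            **{k: _coerce_number(k, data[k]) for k in _INIT_KEYS if k in data}
        )
        grid = SimulationGrid(
            **{k: _coerce_number(k, data[k]) for k in _GRID_KEYS if k in data}
        )
    except (ParameterError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc

    interp = data.get("fig4_l_interpretation", "caption")
    if interp not in ("caption", "text"):
        raise ConfigError(
            f"fig4_l_interpretation must be 'caption' or 'text', got {interp!r}"
        )
    convention = data.get("l2_sign_convention", "eq3")
    if convention not in ("eq3", "eq1"):
        raise ConfigError(
            f"l2_sign_convention must be 'eq3' or 'eq1', got {convention!r}"
        )
    return RunConfig(
        params=params,
        waveform=waveform,
        init=init,
        grid=grid,
        preset=preset,
        fig4_l_interpretation=interp,
        l2_sign_convention=convention,
    )
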