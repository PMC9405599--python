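"""Sphere-approximation geometry and the rupture-risk checklist.

Both sacs are treated as spheres whose volumes are read off the circuit
capacitances, 4*pi*R1^3/3 = C1 and likewise for C2.  The clinical aspect
ratio alpha = depth / neck-width of the resulting dumbbell maps onto the
size ratio through

    alpha = (sqrt(3)/2) * (1 + (C2/C1)^(1/3)),

with neck width w = sqrt(3)*R1 and depth d = (3/2)*(R1 + R2).  The form is
pinned by its two printed anchors: alpha = 1.73 at C2 = C1 and
alpha = 1.67 at C2/C1 = 0.8, which bracket the empirical rupture border
alpha = 1.6 from above and agree with the simulated border C2/C1 = 0.8.

The checklist flags the five morphological/hemodynamic rupture markers:
large aspect ratio, thin/elastic wall (large L1), near-equal daughter
(C2/C1 > 0.8), the solitonic regime (L1 ~ L2, non-decaying pressure wave),
and the to-and-fro resonating regime (large compliance with a daughter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryDomainWarning, ParameterError
from .experiments import SummaryStats
from .model import CircuitParams

__all__ = [
    "ASPECT_RATIO_BORDER",
    "SIZE_RATIO_BORDER",
    "COMPLIANCE_BORDER",
    "RUPTURE_PRESSURE",
    "AneurysmGeometry",
    "RiskReport",
    "radius_from_capacity",
    "aspect_ratio",
    "risk_report",
]

ASPECT_RATIO_BORDER = 1.6  # empirical rupture border on alpha = d/w
SIZE_RATIO_BORDER = 0.80  # simulated rupture border on C2/C1
COMPLIANCE_BORDER = 40.0  # L1 above this marks a thin/elastic wall
RUPTURE_PRESSURE = 180.0  # mmHg; local pressure above this should rupture

#: relative L1-vs-L2 closeness below which a run counts as solitonic
SOLITONIC_REL_TOL = 0.1


def radius_from_capacity(C: float) -> float:
    """Sphere radius with volume C: (3C / 4 pi)^(1/3)."""
    if C < 0:
        raise ParameterError(f"capacity must be >= 0, got {C}")
    return float((3.0 * C / (4.0 * math.pi)) ** (1.0 / 3.0))


def aspect_ratio(size_ratio):
    """Dumbbell aspect ratio alpha = (sqrt(3)/2) * (1 + size_ratio^(1/3)).

    Calibrated on size_ratio = C2/C1 in [0, 1]; outside that range a
    :class:`GeometryDomainWarning` is emitted and the formula is still
    evaluated (cube root taken with sign).
    """
    r = np.asarray(size_ratio, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        warnings.warn(
            "size ratio outside the calibrated domain [0, 1]",
            GeometryDomainWarning,
            stacklevel=2,
        )
    out = (math.sqrt(3.0) / 2.0) * (1.0 + np.cbrt(r))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AneurysmGeometry:
    """Sphere-approximation dumbbell geometry in capacity^(1/3) units."""

    R1: float
    R2: float
    depth_d: float
    neck_w: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if self.R1 <= 0:
            raise ParameterError(f"mother radius must be > 0, got {self.R1}")
        if self.R2 < 0:
            raise ParameterError(f"daughter radius must be >= 0, got {self.R2}")

    @classmethod
    def from_capacities(cls, C1: float, C2: float) -> "AneurysmGeometry":
        R1 = radius_from_capacity(C1)
        R2 = radius_from_capacity(C2)
        w = math.sqrt(3.0) * R1
        d = 1.5 * (R1 + R2)
        return cls(R1=R1, R2=R2, depth_d=d, neck_w=w, aspect_ratio=d / w)


@dataclass(frozen=True)
class RiskReport:
    """Rupture-risk flags, each carrying the quantity that triggered it.

    ``flag_pressure`` applies the 180 mmHg rupture pressure to the
    daughter sac (max P2); ``flag_pressure_single_sac`` is the variant
    applying it to the mother sac (max P1), relevant for single-sac
    compliance runs where no daughter oscillator exists.
    """

    flag_aspect_ratio: bool
    aspect_ratio: float
    flag_daughter_size: bool
    size_ratio: float
    flag_compliance: bool
    L1: float
    flag_pressure: bool
    max_P2: float
    flag_pressure_single_sac: bool
    max_P1: float
    scenario_notes: str

    @property
    def any_flag(self) -> bool:
        return (
            self.flag_aspect_ratio
            or self.flag_daughter_size
            or self.flag_compliance
            or self.flag_pressure
        )

    def to_checklist(self) -> dict[str, dict]:
        """Serialize as the five-item rupture checklist (i)-(v)."""
        solitonic = self.scenario_notes == "solitonic"
        return {
            "i_aspect_ratio": {
                "flag": self.flag_aspect_ratio,
                "quantity": self.aspect_ratio,
                "threshold": ASPECT_RATIO_BORDER,
                "description": "aspect ratio alpha = d/w above the rupture border",
            },
            "ii_thin_or_elastic_wall": {
                "flag": self.flag_compliance,
                "quantity": self.L1,
                "threshold": COMPLIANCE_BORDER,
                "description": "mother compliance L1 above the thin-wall border",
            },
            "iii_daughter_size": {
                "flag": self.flag_daughter_size,
                "quantity": self.size_ratio,
                "threshold": SIZE_RATIO_BORDER,
                "description": "daughter sac at least 80% of the mother",
            },
            "iv_solitonic_regime": {
                "flag": solitonic and self.size_ratio > 0,
                "quantity": self.size_ratio if solitonic else 0.0,
                "threshold": SOLITONIC_REL_TOL,
                "description": (
                    "dumbbell with stiff/thick wall (L1 ~ L2): non-decaying "
                    "solitonic pressure propagation"
                ),
            },
            "v_to_and_fro": {
                "flag": self.flag_compliance and self.size_ratio > 0,
                "quantity": self.L1,
                "threshold": COMPLIANCE_BORDER,
                "description": (
                    "dumbbell with thin/elastic wall: large-amplitude "
                    "to-and-fro resonating oscillation"
                ),
            },
            "pressure": {
                "flag": self.flag_pressure,
                "quantity": self.max_P2,
                "threshold": RUPTURE_PRESSURE,
                "description": "daughter pressure above the rupture pressure",
            },
            "pressure_single_sac": {
                "flag": self.flag_pressure_single_sac,
                "quantity": self.max_P1,
                "threshold": RUPTURE_PRESSURE,
                "description": "mother pressure above the rupture pressure",
            },
        }


def _classify_scenario(params: CircuitParams) -> str:
    Lmax = max(params.L1, params.L2)
    if Lmax > 0 and abs(params.L1 - params.L2) <= SOLITONIC_REL_TOL * Lmax:
        return "solitonic"
    if params.L1 > COMPLIANCE_BORDER:
        return "to-and-fro resonating"
    return "ordinary"


def risk_report(params: CircuitParams, stats: SummaryStats) -> RiskReport:
    """Evaluate the rupture-risk thresholds for one simulated setting.

    ``stats`` must come from a simulation run with the same ``params``.
    """
    alpha = aspect_ratio(params.size_ratio)
    return RiskReport(
        flag_aspect_ratio=alpha > ASPECT_RATIO_BORDER,
        aspect_ratio=float(alpha),
        flag_daughter_size=params.size_ratio > SIZE_RATIO_BORDER,
        size_ratio=params.size_ratio,
        flag_compliance=params.L1 > COMPLIANCE_BORDER,
        L1=params.L1,
        flag_pressure=stats.max_P2 > RUPTURE_PRESSURE,
        max_P2=stats.max_P2,
        flag_pressure_single_sac=stats.max_P1 > RUPTURE_PRESSURE,
        max_P1=stats.max_P1,
        scenario_notes=_classify_scenario(params),
    )
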