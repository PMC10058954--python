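"""Simplified left-ventricular chamber mechanics and circulation.

The 3-D ventricular wall is reduced to a thick-wall Laplace chamber:
cavity volume determines an equivalent radius and a fiber stretch,
active fiber tension maps back to cavity pressure through
``P = 2 T h / r``, and a passive exponential end-diastolic
pressure-volume relation supplies the filling stiffness. The mitral and
aortic valves are ideal diodes with series resistances; the afterload is
a three-element Windkessel (characteristic resistance, peripheral
resistance, arterial compliance). This is the standard desk-scale
reduction that still produces pressure-volume loops, peak pressures and
ejection fractions.

External units are clinical (mmHg, mL, s, cm); fiber tension enters in
kPa and is converted explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import ParameterError, StepSizeError
from .units import KPA_TO_MMHG

__all__ = [
    "LVGeometry",
    "CirculationParams",
    "LVState",
    "fiber_stretch",
    "cavity_radius",
    "passive_pressure",
    "active_pressure",
    "circulation_step",
    "windkessel_steady_pressure",
    "scale_waveform",
]

#: Long-axis/short-axis ratio of the truncated-ellipsoid cavity shape.
ELLIPSOID_ELONGATION = 1.8


@dataclass(frozen=True)
class LVGeometry:
    """Parametric LV phenotype descriptors (volumes mL, lengths cm)."""

    cavity_ref_volume: float  # V0, mL
    wall_thickness: float  # cm
    mitral_diameter: float  # cm
    aortic_diameter: float  # cm
    shape: str = "sphere"

    def __post_init__(self) -> None:
        for f in (
            "cavity_ref_volume",
            "wall_thickness",
            "mitral_diameter",
            "aortic_diameter",
        ):
            if not getattr(self, f) > 0:
                raise ParameterError(f"{f} must be > 0")
        if self.shape not in ("sphere", "truncated-ellipsoid"):
            raise ParameterError(f"unknown shape '{self.shape}'")
        if self.wall_thickness >= cavity_radius(self.cavity_ref_volume, self):
            raise ParameterError(
                "wall_thickness must be smaller than the cavity radius at V0"
            )

    @classmethod
    def from_config(cls, block: Mapping) -> "LVGeometry":
        return cls(
            cavity_ref_volume=block["cavity_ref_volume_ml"],
            wall_thickness=block["wall_thickness_cm"],
            mitral_diameter=block["mitral_diameter_cm"],
            aortic_diameter=block["aortic_diameter_cm"],
            shape=block.get("shape", "sphere"),
        )


@dataclass(frozen=True)
class CirculationParams:
    """Lumped circulation: valves, Windkessel afterload and passive EDPVR."""

    atrial_pressure: float  # mmHg
    mitral_resistance: float  # mmHg*s/mL
    aortic_resistance: float  # Zc, mmHg*s/mL
    peripheral_resistance: float  # Rp, mmHg*s/mL
    arterial_compliance: float  # C, mL/mmHg
    passive_p0: float  # mmHg
    passive_k: float  # 1/mL

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if not getattr(self, f) > 0:
                raise ParameterError(f"{f} must be > 0")

    @classmethod
    def from_config(cls, block: Mapping) -> "CirculationParams":
        return cls(
            atrial_pressure=block["atrial_pressure_mmhg"],
            mitral_resistance=block["mitral_resistance"],
            aortic_resistance=block["aortic_resistance"],
            peripheral_resistance=block["peripheral_resistance"],
            arterial_compliance=block["arterial_compliance"],
            passive_p0=block["passive_p0_mmhg"],
            passive_k=block["passive_k_per_ml"],
        )


@dataclass(frozen=True)
class LVState:
    """Instantaneous chamber/circulation state.

    ``aortic_pressure`` is the pressure at the Windkessel compliance node
    (distal to the characteristic resistance); the proximal arterial
    pressure is ``aortic_pressure + Zc * aortic_flow``.
    """

    cavity_volume: float  # mL
    lv_pressure: float  # mmHg
    aortic_pressure: float  # mmHg
    mitral_flow: float = 0.0  # mL/s
    aortic_flow: float = 0.0  # mL/s
    fiber_stretch: float = 1.0

    def __post_init__(self) -> None:
        if not self.cavity_volume > 0:
            raise ParameterError("cavity_volume must be > 0")
        if self.mitral_flow < 0 or self.aortic_flow < 0:
            raise ParameterError("valve flows must be >= 0 (diode valves)")


def cavity_radius(volume: float, geometry: LVGeometry) -> float:
    """Equivalent cavity radius (cm) used in the Laplace relation.

    Sphere: radius of the sphere of that volume. Truncated ellipsoid:
    equatorial (short-axis) radius of a half prolate spheroid with fixed
    elongation, V = (2/3) pi e b^3.
    """
    if geometry.shape == "sphere":
        return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return (3.0 * volume / (2.0 * math.pi * ELLIPSOID_ELONGATION)) ** (1.0 / 3.0)


def fiber_stretch(volume: float, geometry: LVGeometry) -> float:
    """Fiber stretch relative to the reference volume V0.

    Both shapes scale isotropically with cavity volume, so the stretch is
    the ratio of equivalent radii, (V/V0)^(1/3).
    """
    if not volume > 0:
        raise ParameterError("volume must be > 0")
    return cavity_radius(volume, geometry) / cavity_radius(
        geometry.cavity_ref_volume, geometry
    )


def passive_pressure(
    volume: float, params: CirculationParams, geometry: LVGeometry
) -> float:
    """Passive EDPVR pressure (mmHg): exponential above V0, linear below.

    The linear continuation below V0 matches the slope p0*k at V0, so the
    curve is C1 and strictly increasing everywhere.
    """
    if not volume > 0:
        raise ParameterError("volume must be > 0")
    dv = volume - geometry.cavity_ref_volume
    if dv >= 0:
        return params.passive_p0 * (math.expm1(params.passive_k * dv))
    return params.passive_p0 * params.passive_k * dv


def active_pressure(
    tension: float, volume: float, geometry: LVGeometry
) -> float:
    """Cavity pressure (mmHg) generated by fiber tension (kPa).

    Thick-wall Laplace: P = 2 T h / r with the equivalent radius at the
    current volume; the kPa -> mmHg conversion is applied explicitly.
    """
    if tension < 0:
        raise ParameterError("tension must be >= 0")
    r = cavity_radius(volume, geometry)
    p_kpa = 2.0 * tension * geometry.wall_thickness / r
    return p_kpa * KPA_TO_MMHG


def circulation_step(
    state: LVState,
    lv_pressure: float,
    dt: float,
    params: CirculationParams,
) -> LVState:
    """Advance valves, cavity volume and Windkessel one explicit step.

    Diode valves: the mitral valve opens when atrial pressure exceeds LV
    pressure, the aortic valve when LV pressure exceeds the arterial
    pressure. The volume change over the step equals the net integrated
    flow exactly (explicit Euler), and the compliance node integrates
    aortic inflow minus peripheral run-off.
    """
    if not dt > 0:
        raise ParameterError("dt must be > 0")
    q_mitral = max(0.0, (params.atrial_pressure - lv_pressure) / params.mitral_resistance)
    q_aortic = max(0.0, (lv_pressure - state.aortic_pressure) / params.aortic_resistance)

    volume = state.cavity_volume + dt * (q_mitral - q_aortic)
    if volume <= 0:
        raise StepSizeError(
            f"cavity volume became non-positive ({volume:.3g} mL); reduce dt"
        )
    p_ao = state.aortic_pressure + dt * (
        (q_aortic - state.aortic_pressure / params.peripheral_resistance)
        / params.arterial_compliance
    )
    return replace(
        state,
        cavity_volume=volume,
        lv_pressure=lv_pressure,
        aortic_pressure=p_ao,
        mitral_flow=q_mitral,
        aortic_flow=q_aortic,
    )


def windkessel_steady_pressure(q: float, params: CirculationParams) -> float:
    """Arterial pressure for constant inflow ``q`` at steady state: Q*(Zc+Rp)."""
    return q * (params.aortic_resistance + params.peripheral_resistance)


def scale_waveform(
    waveform: np.ndarray, diameter: float, ref_diameter: float
) -> np.ndarray:
    """Scale a velocity waveform's amplitude proportionally to valve diameter.

    Timing is untouched; only the amplitude is multiplied by
    ``diameter / ref_diameter``.
    """
    if not (diameter > 0 and ref_diameter > 0):
        raise ParameterError("diameters must be > 0")
    return np.asarray(waveform, dtype=float) * (diameter / ref_diameter)
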