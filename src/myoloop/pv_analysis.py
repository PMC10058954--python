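"""Pressure-volume loop metrics and baseline-vs-drug comparisons.

End-diastolic and end-systolic volumes are the extrema of cavity volume
over the final simulated cycle, the ejection fraction is
``LVEF = 100 * (EDV - ESV) / EDV`` and stroke work is the area enclosed
by the P-V loop (shoelace integral of the closed final-cycle polygon,
positive for a normally ejecting, counterclockwise loop).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ParameterError

__all__ = ["PVMetrics", "compute_lvef", "pv_metrics", "loop_shift", "LoopShift"]


@dataclass(frozen=True)
class PVMetrics:
    """Summary of one cardiac cycle's P-V loop."""

    edv: float  # mL
    esv: float  # mL
    stroke_volume: float  # mL
    lvef: float  # percent
    peak_pressure: float  # mmHg
    stroke_work: float  # mmHg*mL
    periodic: bool = True  # False flags a run that had not settled

    def __post_init__(self) -> None:
        if self.esv > self.edv + 1e-9:
            raise ParameterError(f"esv ({self.esv}) must not exceed edv ({self.edv})")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_lvef(edv: float, esv: float) -> float:
    """Ejection fraction in percent, 100 * (EDV - ESV) / EDV."""
    if not edv > 0:
        raise ParameterError("edv must be > 0")
    if not 0 <= esv <= edv:
        raise ParameterError(f"esv must lie in [0, edv], got esv={esv}, edv={edv}")
    return 100.0 * (edv - esv) / edv


def _loop_area(volume: np.ndarray, pressure: np.ndarray) -> float:
    """Signed shoelace area of the closed (V, P) polygon.

    Positive for counterclockwise traversal in the (V, P) plane, which is
    the orientation of an ejecting loop (fill at low pressure, eject at
    high pressure).
    """
    v = np.asarray(volume, float)
    p = np.asarray(pressure, float)
    return 0.5 * float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


def pv_metrics(result) -> PVMetrics:
    """Compute P-V metrics from the final cycle of a simulation result.

    ``result`` is a :class:`myoloop.coupling.SimulationResult` (anything
    with ``volume``, ``p_lv``, ``steps_per_cycle`` and ``periodic``
    attributes works). A non-periodic run is not an error: the metrics
    carry ``periodic=False`` as a warning flag.
    """
    sl = slice(-result.steps_per_cycle - 1, None)
    vol = np.asarray(result.volume[sl], float)
    p = np.asarray(result.p_lv[sl], float)
    if vol.size < 3:
        raise ParameterError("need at least one full cycle of samples")
    edv = float(vol.max())
    esv = float(vol.min())
    return PVMetrics(
        edv=edv,
        esv=esv,
        stroke_volume=edv - esv,
        lvef=compute_lvef(edv, esv),
        peak_pressure=float(p.max()),
        stroke_work=_loop_area(vol, p),
        periodic=bool(getattr(result, "periodic", True)),
    )


@dataclass(frozen=True)
class LoopShift:
    """Signed treated-minus-baseline deltas with direction labels."""

    d_edv: float
    d_esv: float
    d_stroke_volume: float
    d_lvef: float
    d_peak_pressure: float
    d_stroke_work: float
    volume_direction: str  # "toward higher volumes" / "toward lower volumes" / "unchanged"
    pressure_direction: str  # "up" / "down" / "unchanged"

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def loop_shift(baseline: PVMetrics, treated: PVMetrics) -> LoopShift:
    """Elementwise treated-minus-baseline deltas plus direction labels.

    The volume direction is judged by the shift of the loop's mean volume
    (EDV + ESV) / 2; the pressure direction by the peak-pressure delta.
    """
    d_mean_vol = (treated.edv + treated.esv - baseline.edv - baseline.esv) / 2.0
    if abs(d_mean_vol) < 1e-9:
        vdir = "unchanged"
    else:
        vdir = "toward higher volumes" if d_mean_vol > 0 else "toward lower volumes"
    d_pp = treated.peak_pressure - baseline.peak_pressure
    pdir = "unchanged" if abs(d_pp) < 1e-9 else ("up" if d_pp > 0 else "down")
    return LoopShift(
        d_edv=treated.edv - baseline.edv,
        d_esv=treated.esv - baseline.esv,
        d_stroke_volume=treated.stroke_volume - baseline.stroke_volume,
        d_lvef=treated.lvef - baseline.lvef,
        d_peak_pressure=d_pp,
        d_stroke_work=treated.stroke_work - baseline.stroke_work,
        volume_direction=vdir,
        pressure_direction=pdir,
    )
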