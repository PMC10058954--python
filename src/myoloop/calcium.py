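"""Parametric twitch calcium transients and calcium-modulating drugs.

The intracellular calcium transient is the upstream drive of every
contraction simulated by this package. It is represented by a
double-exponential twitch

    ca(t) = ca_base + A * (exp(-(t - t0)/tau_decay) - exp(-(t - t0)/tau_rise))

for t >= t0 and ``ca_base`` before the onset time ``t0``. The amplitude
``A`` is fixed analytically so the curve attains exactly ``ca_peak`` at
``t_peak``; the onset latency ``t0 = t_peak - t*`` (with ``t*`` the
analytic peak location of the double exponential) lets the same family
describe both a trabecula twitch stimulated at t = 0 and the
diastole-first timing of a chamber cycle where systole starts late.

Calcium-modulating drugs (scenario 1) act purely on this curve:
Disopyramide lowers peak and basal calcium; Digoxin raises the twitch
peak while leaving time-to-peak and relaxation untouched. Dose is mapped
to scale factors through a saturating Hill relation whose per-drug
constants live in the package config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .config import load_defaults
from .errors import DrugError, ParameterError

__all__ = [
    "CalciumTransient",
    "CalciumDrugSpec",
    "make_transient",
    "apply_calcium_drug",
    "dose_to_scales",
    "transient_to_frame",
]


@dataclass(frozen=True)
class CalciumTransient:
    """Parameters of one twitch calcium transient (concentrations µmol/L, times s)."""

    ca_base: float
    ca_peak: float
    t_peak: float
    tau_rise: float
    tau_decay: float
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        if not self.ca_base >= 0:
            raise ParameterError(f"ca_base must be >= 0, got {self.ca_base}")
        if not self.ca_peak > self.ca_base:
            raise ParameterError(
                f"ca_peak ({self.ca_peak}) must exceed ca_base ({self.ca_base})"
            )
        if not (0 < self.t_peak < self.cycle_length):
            raise ParameterError(
                f"t_peak ({self.t_peak}) must lie in (0, cycle_length={self.cycle_length})"
            )
        if not (self.tau_rise > 0 and self.tau_decay > 0):
            raise ParameterError("tau_rise and tau_decay must be > 0")
        if not self.tau_decay > self.tau_rise:
            raise ParameterError(
                f"tau_decay ({self.tau_decay}) must exceed tau_rise ({self.tau_rise}) "
                "for a twitch-shaped transient"
            )
        if self.onset_time < -1e-12:
            raise ParameterError(
                f"time constants place the intrinsic peak at {self.intrinsic_peak_time:.4g} s, "
                f"after the requested t_peak {self.t_peak:.4g} s; "
                "shorten tau_rise/tau_decay or move t_peak later"
            )

    @property
    def intrinsic_peak_time(self) -> float:
        """Peak location t* of exp(-t/tau_d) - exp(-t/tau_r) measured from onset."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def onset_time(self) -> float:
        """Latency between cycle start and the upstroke of the transient."""
        return self.t_peak - self.intrinsic_peak_time

    @property
    def amplitude(self) -> float:
        """Analytic normalisation constant A such that max ca(t) = ca_peak."""
        ts = self.intrinsic_peak_time
        gmax = math.exp(-ts / self.tau_decay) - math.exp(-ts / self.tau_rise)
        return (self.ca_peak - self.ca_base) / gmax

    def __call__(self, t):
        """Evaluate the transient at scalar or array time ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        s = np.maximum(t - self.onset_time, 0.0)
        g = np.exp(-s / self.tau_decay) - np.exp(-s / self.tau_rise)
        out = self.ca_base + self.amplitude * g
        return out if out.ndim else float(out)


def make_transient(params: CalciumTransient, t: np.ndarray) -> np.ndarray:
    """Evaluate ``params`` on the time grid ``t`` covering [0, cycle_length]."""
    t = np.asarray(t, dtype=float)
    if t.size < 2 or t[0] > 1e-12 or t[-1] < params.cycle_length - 1e-9:
        raise ParameterError(
            "time grid must cover [0, cycle_length] "
            f"(got [{t[0]}, {t[-1]}], cycle_length={params.cycle_length})"
        )
    return params(t)


@dataclass(frozen=True)
class CalciumDrugSpec:
    """Multiplicative action of a calcium-modulating drug on a transient."""

    name: str
    dose: float
    scale_peak: float
    scale_base: float
    scale_times: float = 1.0

    def __post_init__(self) -> None:
        for field in ("scale_peak", "scale_base", "scale_times"):
            if not getattr(self, field) > 0:
                raise ParameterError(f"{field} must be > 0")
        if self.dose < 0:
            raise ParameterError("dose must be >= 0")


def apply_calcium_drug(
    transient: CalciumTransient, drug: CalciumDrugSpec
) -> CalciumTransient:
    """Return a new transient with the drug's scale factors applied.

    Peak and basal calcium are scaled independently; ``scale_times``
    scales all the timing parameters (t_peak and both time constants)
    together, so a pure amplitude drug such as Digoxin leaves the
    time-to-peak and relaxation untouched. The input is not mutated.
    """
    new_peak = drug.scale_peak * transient.ca_peak
    new_base = drug.scale_base * transient.ca_base
    if new_peak <= new_base:
        raise DrugError(
            f"drug '{drug.name}' leaves ca_peak' ({new_peak:.4g}) <= ca_base' "
            f"({new_base:.4g}): the scaled transient has no twitch"
        )
    return replace(
        transient,
        ca_peak=new_peak,
        ca_base=new_base,
        t_peak=drug.scale_times * transient.t_peak,
        tau_rise=drug.scale_times * transient.tau_rise,
        tau_decay=drug.scale_times * transient.tau_decay,
    )


def _hill_scale(dose: float, ec50: float, sat: float) -> float:
    # Hill coefficient 1: dose 0 -> 1, dose -> inf -> sat, monotone in between.
    return 1.0 + (sat - 1.0) * dose / (ec50 + dose)


def dose_to_scales(
    drug_name: str, dose: float, registry: Mapping | None = None
) -> CalciumDrugSpec:
    """Map a dose to a :class:`CalciumDrugSpec` via the drug registry.

    Each registered drug stores an EC50 and saturation scale factors; the
    dose-response is a Hill curve with coefficient 1, so zero dose gives
    identity scales and the saturation values are approached monotonically.
    """
    if dose < 0:
        raise ParameterError("dose must be >= 0")
    if registry is None:
        registry = load_defaults()["calcium_drugs"]
    key = drug_name.lower()
    if key not in registry:
        raise DrugError(
            f"unknown calcium drug '{drug_name}'; registered: {sorted(registry)}"
        )
    entry = registry[key]
    ec50 = entry["ec50_umol_per_l"]
    return CalciumDrugSpec(
        name=key,
        dose=dose,
        scale_peak=_hill_scale(dose, ec50, entry["sat_scale_peak"]),
        scale_base=_hill_scale(dose, ec50, entry["sat_scale_base"]),
        scale_times=_hill_scale(dose, ec50, entry["sat_scale_times"]),
    )


def transient_to_frame(params: CalciumTransient, t: np.ndarray):
    """Two-column DataFrame (time_s, ca_umol_per_L) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {"time_s": np.asarray(t, float), "ca_umol_per_L": make_transient(params, t)}
    )
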