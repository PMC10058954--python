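"""Three-state crossbridge surrogate of sarcomere contraction.

Myosin heads are partitioned into three populations:

* ``parked`` — the autoinhibited, ordered OFF (super-relaxed, SRX)
  configuration, unavailable for actin binding;
* ``detached`` — disordered ON (DRX) heads, available to attach;
* ``attached`` — force-bearing crossbridges.

The populations exchange through first-order master equations::

    parked  <-- k_on_to_off --  detached            (constitutive)
    parked  -- k_off_to_on -->  detached
    detached -- k_attach * activation --> attached
    attached -- k_detach * exp(sens * |distortion|) --> detached

``activation`` is a Hill function of calcium with a length-dependent
half-activation point (longer sarcomeres are more calcium sensitive),
representing thin-filament regulation. A scalar mean-distortion variable
(nm, zero at isometric steady state) carries the force-velocity effect:
shortening drives it negative, lowering force and speeding detachment.

Active tension is ``t_max * attached * overlap(stretch) * distortion
factor``; instantaneous stiffness is proportional to the attached
fraction. Drugs of the kinetic class (Mavacamten, dATP) multiply the
four transition rates — Mavacamten biases heads into the parked state,
dATP enhances attachment and destabilises the parked state.

This is deliberately the minimal structure that exposes every drug hook
of the two in-silico trial scenarios; it does not resolve the filament
lattice or sample individual crossbridges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.linalg import expm

from .calcium import CalciumTransient
from .config import load_defaults
from .errors import DrugError, ParameterError, StepSizeError

__all__ = [
    "SarcomereState",
    "KineticParams",
    "KineticDrugSpec",
    "TensionResult",
    "TwitchResult",
    "thin_filament_activation",
    "rate_matrix",
    "step_state",
    "steady_state",
    "active_tension",
    "steady_state_tension",
    "apply_kinetic_drug",
    "kinetic_dose_to_scales",
    "simulate_twitch",
]

#: Mean elastic strain of an attached head at isometric steady state (nm);
#: sets the scale on which distortion modulates force.
POWER_STROKE_NM = 5.0

#: Distortion driven by stretch rate: target offset = this constant times
#: the fiber stretch rate (nm per unit stretch/s). Chosen so physiological
#: ejection-phase shortening (~0.5/s) depresses force by ~20%.
DISTORTION_VELOCITY_SCALE_NM_S = 2.0

#: Linear length-dependence of calcium sensitivity: ca50 is reduced by
#: this fraction per unit of stretch above 1 (and raised below).
LENGTH_SENSITIVITY = 1.0

#: Stretch at which myofilament overlap is maximal.
OPTIMAL_STRETCH = 1.05

_CONSERVATION_TOL = 1e-10

#: Cap on the strain amplification exp(sens * |distortion|) of the detach
#: rate; strained-head detachment saturates instead of diverging.
_MAX_STRAIN_FACTOR = 10.0


def _effective_detach_rate(params: "KineticParams", distortion: float) -> float:
    factor = min(
        math.exp(params.detach_strain_sensitivity * abs(distortion)),
        _MAX_STRAIN_FACTOR,
    )
    return params.k_detach * factor


@dataclass(frozen=True)
class SarcomereState:
    """Crossbridge population fractions plus mean distortion (nm)."""

    frac_parked: float
    frac_detached: float
    frac_attached: float
    mean_distortion: float = 0.0

    def __post_init__(self) -> None:
        fr = (self.frac_parked, self.frac_detached, self.frac_attached)
        if any(f < -1e-12 or f > 1 + 1e-12 for f in fr):
            raise ParameterError(f"state fractions must lie in [0, 1], got {fr}")
        if abs(sum(fr) - 1.0) > 1e-8:
            raise ParameterError(f"state fractions must sum to 1, got {sum(fr)}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array(
            [self.frac_parked, self.frac_detached, self.frac_attached], float
        )


@dataclass(frozen=True)
class KineticParams:
    """Transition rates and mechanical constants of the surrogate."""

    k_off_to_on: float
    k_on_to_off: float
    k_attach: float
    k_detach: float
    detach_strain_sensitivity: float
    t_max: float
    ca50: float
    hill_h: float
    overlap_width: float
    stiffness_per_attached: float

    def __post_init__(self) -> None:
        positive = (
            "k_off_to_on",
            "k_on_to_off",
            "k_attach",
            "k_detach",
            "t_max",
            "ca50",
            "overlap_width",
            "stiffness_per_attached",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.detach_strain_sensitivity < 0:
            raise ParameterError("detach_strain_sensitivity must be >= 0")
        if self.hill_h < 1:
            raise ParameterError(f"hill_h must be >= 1, got {self.hill_h}")

    @classmethod
    def from_config(cls, block: Mapping) -> "KineticParams":
        return cls(
            k_off_to_on=block["k_off_to_on_per_s"],
            k_on_to_off=block["k_on_to_off_per_s"],
            k_attach=block["k_attach_per_s"],
            k_detach=block["k_detach_per_s"],
            detach_strain_sensitivity=block["detach_strain_sensitivity_per_nm"],
            t_max=block["t_max_kpa"],
            ca50=block["ca50_umol_per_l"],
            hill_h=block["hill_h"],
            overlap_width=block["overlap_width"],
            stiffness_per_attached=block["stiffness_per_attached_kpa"],
        )


@dataclass(frozen=True)
class KineticDrugSpec:
    """Multiplicative action of a kinetics-modulating drug on the rates."""

    name: str
    dose: float
    scale_off_to_on: float = 1.0
    scale_on_to_off: float = 1.0
    scale_attach: float = 1.0
    scale_detach: float = 1.0

    def __post_init__(self) -> None:
        for f in ("scale_off_to_on", "scale_on_to_off", "scale_attach", "scale_detach"):
            if not getattr(self, f) > 0:
                raise ParameterError(f"{f} must be > 0")
        if self.dose < 0:
            raise ParameterError("dose must be >= 0")


@dataclass(frozen=True)
class TensionResult:
    active_tension: float  # kPa
    instantaneous_stiffness: float  # kPa per unit stretch


def thin_filament_activation(
    ca: float, stretch: float, params: KineticParams
) -> float:
    """Hill activation of the thin filament with length-dependent ca50.

    Returns a value in [0, 1]. The half-activation concentration falls
    linearly with stretch above 1 (length-dependent activation), floored
    at 20% of the nominal ca50.
    """
    if ca < 0:
        raise ParameterError("ca must be >= 0")
    if not stretch > 0:
        raise ParameterError("stretch must be > 0")
    ca50_eff = params.ca50 * max(1.0 - LENGTH_SENSITIVITY * (stretch - 1.0), 0.2)
    if ca == 0.0:
        return 0.0
    r = (ca / ca50_eff) ** params.hill_h
    return r / (1.0 + r)


def overlap(stretch: float, params: KineticParams) -> float:
    """Symmetric myofilament-overlap factor in [0, 1], peaking at the optimum."""
    z = (stretch - OPTIMAL_STRETCH) / params.overlap_width
    return max(0.0, 1.0 - z * z)


def rate_matrix(
    ca: float,
    stretch: float,
    params: KineticParams,
    distortion: float = 0.0,
) -> np.ndarray:
    """Generator Q of the 3-state master equation, d/dt [P, D, A] = Q @ [P, D, A].

    Columns sum to zero, so population is conserved exactly.
    """
    act = thin_filament_activation(ca, stretch, params)
    kf = params.k_off_to_on
    kb = params.k_on_to_off
    ka = params.k_attach * act
    kd = _effective_detach_rate(params, distortion)
    return np.array(
        [
            [-kf, kb, 0.0],
            [kf, -(kb + ka), kd],
            [0.0, ka, -kd],
        ]
    )


def step_state(
    state: SarcomereState,
    ca: float,
    stretch: float,
    stretch_rate: float,
    dt: float,
    params: KineticParams,
) -> SarcomereState:
    """Advance the state one step of size ``dt``.

    The linear state exchange uses the exact exponential of the generator
    frozen over the step (unconditionally conservative); the distortion
    relaxes exponentially toward its stretch-rate-driven target at the
    effective detach rate. ``dt`` times the effective detach rate must
    stay below 1 for the frozen-rate splitting to remain accurate.
    """
    if not dt > 0:
        raise ParameterError("dt must be > 0")
    x = state.mean_distortion
    kd_eff = _effective_detach_rate(params, x)
    if dt * kd_eff >= 1.0:
        raise StepSizeError(
            f"dt={dt} too large for the frozen-rate distortion update "
            f"(dt * effective detach rate = {dt * kd_eff:.3g} >= 1); reduce dt"
        )
    q = rate_matrix(ca, stretch, params, distortion=x)
    s = expm(q * dt) @ state.fractions

    clipped = -s[s < 0].sum()
    if clipped > 1e-6:
        raise StepSizeError(
            f"state fraction went negative by {clipped:.3g}; reduce dt"
        )
    if clipped > 1e-8:
        warnings.warn(
            f"clipped negative state fractions totalling {clipped:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    s = np.clip(s, 0.0, None)
    s /= s.sum()

    x_target = DISTORTION_VELOCITY_SCALE_NM_S * stretch_rate
    x_new = x_target + (x - x_target) * math.exp(-kd_eff * dt)

    return SarcomereState(
        frac_parked=s[0],
        frac_detached=s[1],
        frac_attached=s[2],
        mean_distortion=x_new,
    )


def steady_state(
    ca: float,
    stretch: float,
    params: KineticParams,
    distortion: float = 0.0,
) -> SarcomereState:
    """Algebraic fixed point of the master equation at constant drive."""
    q = rate_matrix(ca, stretch, params, distortion=distortion)
    a = np.vstack([q[:2], np.ones(3)])
    s = np.linalg.solve(a, np.array([0.0, 0.0, 1.0]))
    s = np.clip(s, 0.0, None)
    s /= s.sum()
    return SarcomereState(s[0], s[1], s[2], mean_distortion=distortion)


def active_tension(
    state: SarcomereState, stretch: float, params: KineticParams
) -> TensionResult:
    """Active fiber tension (kPa) and instantaneous stiffness.

    Tension is the product of maximal tension, attached fraction, the
    overlap factor and a distortion factor (1 at isometric steady state).
    """
    distortion_factor = max(0.0, 1.0 + state.mean_distortion / POWER_STROKE_NM)
    tension = (
        params.t_max
        * state.frac_attached
        * overlap(stretch, params)
        * distortion_factor
    )
    stiffness = params.stiffness_per_attached * state.frac_attached
    return TensionResult(active_tension=tension, instantaneous_stiffness=stiffness)


def steady_state_tension(
    ca: float, stretch: float, params: KineticParams
) -> float:
    """Tension (kPa) at the algebraic fixed point for constant calcium."""
    st = steady_state(ca, stretch, params)
    return active_tension(st, stretch, params).active_tension


def apply_kinetic_drug(
    params: KineticParams, drug: KineticDrugSpec
) -> KineticParams:
    """Return new kinetics with the drug's rate scale factors applied."""
    return replace(
        params,
        k_off_to_on=params.k_off_to_on * drug.scale_off_to_on,
        k_on_to_off=params.k_on_to_off * drug.scale_on_to_off,
        k_attach=params.k_attach * drug.scale_attach,
        k_detach=params.k_detach * drug.scale_detach,
    )


def kinetic_dose_to_scales(
    drug_name: str, dose: float, registry: Mapping | None = None
) -> KineticDrugSpec:
    """Map a dose to a :class:`KineticDrugSpec` via the drug registry.

    Same saturating Hill dose-response convention as the calcium drugs.
    """
    if dose < 0:
        raise ParameterError("dose must be >= 0")
    if registry is None:
        registry = load_defaults()["kinetic_drugs"]
    key = drug_name.lower()
    if key not in registry:
        raise DrugError(
            f"unknown kinetic drug '{drug_name}'; registered: {sorted(registry)}"
        )
    entry = registry[key]
    ec50 = entry.get("ec50_umol_per_l", entry.get("ec50_pct"))

    def scale(sat):
        return 1.0 + (sat - 1.0) * dose / (ec50 + dose)

    return KineticDrugSpec(
        name=key,
        dose=dose,
        scale_off_to_on=scale(entry["sat_scale_off_to_on"]),
        scale_on_to_off=scale(entry["sat_scale_on_to_off"]),
        scale_attach=scale(entry["sat_scale_attach"]),
        scale_detach=scale(entry["sat_scale_detach"]),
    )


@dataclass
class TwitchResult:
    """Time course of one simulated twitch (isometric unless a protocol is given)."""

    time: np.ndarray
    tension: np.ndarray  # kPa
    stiffness: np.ndarray  # kPa
    frac_parked: np.ndarray
    frac_detached: np.ndarray
    frac_attached: np.ndarray

    @property
    def peak_tension(self) -> float:
        return float(self.tension.max())

    @property
    def time_to_peak(self) -> float:
        return float(self.time[int(self.tension.argmax())])

    @property
    def resting_tension(self) -> float:
        """Tension at the end of the cycle (back at basal calcium)."""
        return float(self.tension[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "tension_kPa": self.tension,
                "stiffness_kPa": self.stiffness,
                "frac_parked": self.frac_parked,
                "frac_detached": self.frac_detached,
                "frac_attached": self.frac_attached,
            }
        )


def simulate_twitch(
    transient: CalciumTransient,
    params: KineticParams,
    stretch_protocol: float | np.ndarray = 1.0,
    dt: float = 1e-3,
) -> TwitchResult:
    """Simulate one twitch driven by a calcium transient.

    ``stretch_protocol`` is either a constant (isometric) or a stretch
    series on the implied time grid. The initial state is the resting
    steady state at basal calcium, so resting tension is well defined.
    """
    n = int(round(transient.cycle_length / dt)) + 1
    t = np.linspace(0.0, transient.cycle_length, n)
    if np.isscalar(stretch_protocol):
        stretch = np.full(n, float(stretch_protocol))
    else:
        stretch = np.asarray(stretch_protocol, dtype=float)
        if stretch.shape != t.shape:
            raise ParameterError(
                f"stretch protocol length {stretch.size} != time grid length {n}"
            )
    stretch_rate = np.gradient(stretch, t)
    ca = transient(t)

    state = steady_state(ca[0], stretch[0], params)
    tension = np.empty(n)
    stiffness = np.empty(n)
    fracs = np.empty((n, 3))

    res = active_tension(state, stretch[0], params)
    tension[0], stiffness[0] = res.active_tension, res.instantaneous_stiffness
    fracs[0] = state.fractions

    for k in range(1, n):
        state = step_state(
            state, ca[k], stretch[k], stretch_rate[k], t[k] - t[k - 1], params
        )
        res = active_tension(state, stretch[k], params)
        tension[k], stiffness[k] = res.active_tension, res.instantaneous_stiffness
        fracs[k] = state.fractions

    return TwitchResult(
        time=t,
        tension=tension,
        stiffness=stiffness,
        frac_parked=fracs[:, 0],
        frac_detached=fracs[:, 1],
        frac_attached=fracs[:, 2],
    )
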