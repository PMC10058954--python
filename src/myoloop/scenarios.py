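"""Synthetic phenotype fixtures and end-to-end drug-trial scenarios.

Real patient measurements behind the HCM/DCM models are not available,
so phenotypes are generated synthetically: each label (``hcm``, ``dcm``,
``normal``) has committed defaults in the package config — HCM a small,
thick-walled, stiff cavity with elevated diastolic calcium; DCM an
enlarged, thin-walled, hypocontractile one — and a seeded multiplicative
jitter emulates between-patient variability. Generation is fully
deterministic given (label, seed, jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .calcium import CalciumTransient
from .chamber import CirculationParams, LVGeometry, scale_waveform
from .config import load_defaults
from .errors import ParameterError
from .sarcomere import KineticParams

__all__ = [
    "PhenotypeSpec",
    "generate_phenotype",
    "generate_waveforms",
    "twitch_transient",
    "write_scenario_dir",
]

PHENOTYPE_LABELS = ("hcm", "dcm", "normal")

# Fields perturbed by the jitter (multiplicative, uniform in [1-j, 1+j]).
_GEOMETRY_JITTER = ("cavity_ref_volume", "wall_thickness", "mitral_diameter", "aortic_diameter")
_KINETIC_JITTER = ("k_attach", "k_detach", "t_max")
_CALCIUM_JITTER = ("ca_peak",)


@dataclass(frozen=True)
class PhenotypeSpec:
    """One synthetic patient: geometry, kinetics, calcium drive, circulation."""

    label: str
    geometry: LVGeometry
    kinetics: KineticParams
    calcium: CalciumTransient
    circulation: CirculationParams
    seed: int = 0


def generate_phenotype(label: str, seed: int = 0, jitter: float = 0.0) -> PhenotypeSpec:
    """Build a phenotype spec from committed defaults plus seeded jitter.

    ``jitter`` (a fraction in [0, 0.3]) multiplies geometry, contractile
    and calcium-amplitude parameters by independent factors drawn
    uniformly from [1 - jitter, 1 + jitter] with a generator seeded from
    ``seed``; jitter 0 returns the exact defaults. The same (label,
    seed, jitter) always yields the identical spec.
    """
    key = label.lower()
    if key not in PHENOTYPE_LABELS:
        raise ParameterError(
            f"unknown phenotype label '{label}'; expected one of {PHENOTYPE_LABELS}"
        )
    if not 0.0 <= jitter <= 0.3:
        raise ParameterError(f"jitter must lie in [0, 0.3], got {jitter}")

    cfg = load_defaults()["phenotypes"][key]
    geometry = LVGeometry.from_config(cfg["geometry"])
    kinetics = KineticParams.from_config(cfg["kinetics"])
    cal = cfg["calcium"]
    calcium = CalciumTransient(
        ca_base=cal["ca_base_umol_per_l"],
        ca_peak=cal["ca_peak_umol_per_l"],
        t_peak=cal["t_peak_s"],
        tau_rise=cal["tau_rise_s"],
        tau_decay=cal["tau_decay_s"],
        cycle_length=load_defaults()["time"]["cycle_length_s"],
    )
    circulation = CirculationParams.from_config(cfg["circulation"])

    if jitter > 0:
        rng = np.random.default_rng(seed)

        def perturb(obj, fields):
            factors = {
                f: getattr(obj, f) * rng.uniform(1.0 - jitter, 1.0 + jitter)
                for f in fields
            }
            return replace(obj, **factors)

        geometry = perturb(geometry, _GEOMETRY_JITTER)
        kinetics = perturb(kinetics, _KINETIC_JITTER)
        calcium = perturb(calcium, _CALCIUM_JITTER)

    return PhenotypeSpec(
        label=key,
        geometry=geometry,
        kinetics=kinetics,
        calcium=calcium,
        circulation=circulation,
        seed=seed,
    )


def twitch_transient(spec: PhenotypeSpec, t_peak: float = 0.05) -> CalciumTransient:
    """The phenotype's calcium transient re-timed for a trabecula twitch.

    Chamber-cycle transients place systole late in the cycle (diastole
    first); an isometric twitch experiment stimulates at t = 0, so the
    peak is moved to ``t_peak`` with amplitudes and time constants
    untouched.
    """
    return replace(spec.calcium, t_peak=t_peak)


def generate_waveforms(
    geometry: LVGeometry, cycle_length: float = 1.0, n: int = 1001
) -> "pd.DataFrame":
    """Nominal inlet/outlet valve velocity waveforms scaled to the geometry.

    Raised-cosine pulses: an E-wave-like diastolic inflow and a systolic
    outflow in disjoint windows of the cycle. Amplitudes are the nominal
    peak velocities scaled proportionally to the mitral (inlet) and
    aortic (outlet) valve diameters. Returns a DataFrame with columns
    ``time_s``, ``inlet_cm_s``, ``outlet_cm_s``.
    """
    import pandas as pd

    wf = load_defaults()["waveforms"]
    t = np.linspace(0.0, cycle_length, n)

    def pulse(window, peak):
        lo, hi = window
        out = np.zeros_like(t)
        inside = (t >= lo) & (t <= hi)
        out[inside] = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[inside] - lo) / (hi - lo)))
        return out

    inlet = pulse(wf["diastole_window_s"], wf["peak_inlet_velocity_cm_s"])
    outlet = pulse(wf["systole_window_s"], wf["peak_outlet_velocity_cm_s"])
    inlet = scale_waveform(inlet, geometry.mitral_diameter, wf["ref_mitral_diameter_cm"])
    outlet = scale_waveform(outlet, geometry.aortic_diameter, wf["ref_aortic_diameter_cm"])
    return pd.DataFrame({"time_s": t, "inlet_cm_s": inlet, "outlet_cm_s": outlet})


def write_scenario_dir(spec: PhenotypeSpec, path: str | Path) -> Path:
    """Write a scenario directory: phenotype YAML + waveform CSV.

    Every output records the generating seed in its header so fixtures
    are reproducible from the files alone.
    """
    import yaml

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "label": spec.label,
        "seed": spec.seed,
        "geometry": vars(spec.geometry).copy(),
        "kinetics": vars(spec.kinetics).copy(),
        "calcium": vars(spec.calcium).copy(),
        "circulation": vars(spec.circulation).copy(),
    }
    with open(path / "phenotype.yaml", "w") as fh:
        fh.write(f"# myoloop scenario '{spec.label}', seed={spec.seed}\n")
        yaml.safe_dump(meta, fh, sort_keys=False)
    wf = generate_waveforms(spec.geometry)
    with open(path / "waveforms.csv", "w") as fh:
        fh.write(f"# myoloop waveforms for '{spec.label}', seed={spec.seed}\n")
        wf.to_csv(fh, index=False)
    return path
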