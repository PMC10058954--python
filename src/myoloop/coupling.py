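"""Incremental-iterative loose coupling of chamber and sarcomere.

Each time step alternates between the two sub-models until a fixed
point is reached, mirroring partitioned fluid-structure coupling:

1. propose an end-of-step cavity volume and compute the fiber stretch
   and stretch rate it implies;
2. the sarcomere surrogate advances one step at that stretch and returns
   active tension and instantaneous stiffness;
3. chamber mechanics converts tension to cavity pressure, and the
   valve/Windkessel circulation yields the new volume.

The inner iteration is damped successive substitution on the proposed
volume (relaxation factor configurable); it stops when the relative
changes of active tension and of outflow velocity both fall below their
tolerances. The whole pipeline is deterministic: a seed only enters
through fixture generation, never the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__ as _pkg_version
from .calcium import CalciumTransient
from .chamber import (
    CirculationParams,
    LVGeometry,
    LVState,
    active_pressure,
    circulation_step,
    fiber_stretch,
    passive_pressure,
)
from .errors import ConvergenceError, ParameterError
from .pv_analysis import PVMetrics, LoopShift, loop_shift, pv_metrics
from .sarcomere import (
    KineticDrugSpec,
    KineticParams,
    active_tension,
    apply_kinetic_drug,
    step_state,
    steady_state,
)
from .calcium import CalciumDrugSpec, apply_calcium_drug

__all__ = [
    "CouplingConfig",
    "SimulationResult",
    "DrugComparison",
    "run_cycle",
    "run_drug_comparison",
]

# Absolute floors for the relative convergence norms, so phases with
# (near-)zero tension or flow do not stall the inner iteration.
_TENSION_FLOOR_KPA = 1e-3
_VELOCITY_FLOOR_CM_S = 1e-3


@dataclass(frozen=True)
class CouplingConfig:
    """Numerical controls of the coupled simulation."""

    dt: float = 1e-3  # s
    tol_velocity: float = 1e-4  # relative change of outflow velocity
    tol_tension: float = 1e-4  # relative change of active tension
    max_inner_iter: int = 50
    n_cycles: int = 10
    seed: int = 0
    relaxation: float = 0.5
    periodic_edv_tol: float = 0.005  # cycle-to-cycle relative EDV change

    def __post_init__(self) -> None:
        if not (self.tol_velocity > 0 and self.tol_tension > 0):
            raise ParameterError("tolerances must be > 0")
        if self.max_inner_iter < 1:
            raise ParameterError("max_inner_iter must be >= 1")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if not (0 < self.relaxation <= 1):
            raise ParameterError("relaxation must lie in (0, 1]")
        if not self.dt > 0:
            raise ParameterError("dt must be > 0")


@dataclass
class SimulationResult:
    """Shared-grid time series of a coupled run plus solver diagnostics."""

    time: np.ndarray  # s
    volume: np.ndarray  # mL
    p_lv: np.ndarray  # mmHg
    p_ao: np.ndarray  # mmHg (Windkessel compliance node)
    q_mitral: np.ndarray  # mL/s
    q_aortic: np.ndarray  # mL/s
    stretch: np.ndarray
    tension: np.ndarray  # kPa
    stiffness: np.ndarray  # kPa
    frac_parked: np.ndarray
    frac_detached: np.ndarray
    frac_attached: np.ndarray
    distortion: np.ndarray  # nm
    inner_iterations: np.ndarray  # per step
    steps_per_cycle: int
    periodic: bool
    edv_per_cycle: np.ndarray
    config: CouplingConfig = field(repr=False, default=None)
    version: str = _pkg_version

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "volume_mL": self.volume,
                "p_lv_mmHg": self.p_lv,
                "p_ao_mmHg": self.p_ao,
                "q_mitral_mL_s": self.q_mitral,
                "q_aortic_mL_s": self.q_aortic,
                "stretch": self.stretch,
                "tension_kPa": self.tension,
            }
        )


def run_cycle(
    calcium: CalciumTransient,
    kinetics: KineticParams,
    geometry: LVGeometry,
    circulation: CirculationParams,
    config: CouplingConfig = CouplingConfig(),
) -> SimulationResult:
    """Run ``config.n_cycles`` coupled cardiac cycles.

    Returns the full time series and flags whether a periodic steady
    state was reached (relative cycle-to-cycle change of end-diastolic
    volume below ``config.periodic_edv_tol``).

    Raises :class:`ConvergenceError` (with the residual history of the
    offending step) if an inner iteration hits ``max_inner_iter``.
    """
    dt = config.dt
    cl = calcium.cycle_length
    steps_per_cycle = int(round(cl / dt))
    n_steps = steps_per_cycle * config.n_cycles
    t = np.arange(n_steps + 1) * dt

    outflow_area = math.pi * geometry.aortic_diameter**2 / 4.0  # cm^2

    # Initial conditions: rest at basal calcium, reference volume,
    # diastolic arterial pressure; transients settle over the first cycles.
    v = geometry.cavity_ref_volume
    lam = fiber_stretch(v, geometry)
    s_state = steady_state(calcium(0.0), lam, kinetics)
    ten0 = active_tension(s_state, lam, kinetics)
    p_lv0 = passive_pressure(v, circulation, geometry) + active_pressure(
        ten0.active_tension, v, geometry
    )
    state = LVState(
        cavity_volume=v, lv_pressure=p_lv0, aortic_pressure=70.0, fiber_stretch=lam
    )

    n = n_steps + 1
    rec = {
        k: np.empty(n)
        for k in (
            "volume",
            "p_lv",
            "p_ao",
            "q_mitral",
            "q_aortic",
            "stretch",
            "tension",
            "stiffness",
            "fp",
            "fd",
            "fa",
            "dist",
        )
    }
    iters = np.zeros(n_steps, dtype=int)

    def record(k, st: LVState, ten, s):
        rec["volume"][k] = st.cavity_volume
        rec["p_lv"][k] = st.lv_pressure
        rec["p_ao"][k] = st.aortic_pressure
        rec["q_mitral"][k] = st.mitral_flow
        rec["q_aortic"][k] = st.aortic_flow
        rec["stretch"][k] = st.fiber_stretch
        rec["tension"][k] = ten.active_tension
        rec["stiffness"][k] = ten.instantaneous_stiffness
        rec["fp"][k], rec["fd"][k], rec["fa"][k] = s.fractions
        rec["dist"][k] = s.mean_distortion

    record(0, state, ten0, s_state)

    v_prev_step = state.cavity_volume
    for k in range(1, n):
        ca1 = calcium(t[k] % cl)
        lam_n = state.fiber_stretch
        # Linear extrapolation of the volume as the initial inner guess.
        v_end = state.cavity_volume + (state.cavity_volume - v_prev_step)
        ten_prev = None
        vout_prev = None
        v_old = None
        f_old = None
        history = []
        converged = False
        for i in range(1, config.max_inner_iter + 1):
            lam_end = fiber_stretch(v_end, geometry)
            lam_rate = (lam_end - lam_n) / dt
            s_try = step_state(s_state, ca1, lam_end, lam_rate, dt, kinetics)
            ten = active_tension(s_try, lam_end, kinetics)
            p_lv = passive_pressure(v_end, circulation, geometry) + active_pressure(
                ten.active_tension, v_end, geometry
            )
            new_state = circulation_step(state, p_lv, dt, circulation)
            v_new = new_state.cavity_volume
            v_out = new_state.aortic_flow / outflow_area  # cm/s

            if ten_prev is not None:
                res_t = abs(ten.active_tension - ten_prev) / max(
                    abs(ten.active_tension), _TENSION_FLOOR_KPA
                )
                res_v = abs(v_out - vout_prev) / max(abs(v_out), _VELOCITY_FLOOR_CM_S)
                history.append((res_t, res_v))
                if res_t < config.tol_tension and res_v < config.tol_velocity:
                    converged = True
            ten_prev = ten.active_tension
            vout_prev = v_out
            if converged:
                break
            # Fixed-point residual of the proposed end-of-step volume.
            f_cur = v_new - v_end
            v_next = None
            if f_old is not None and abs(f_cur - f_old) > 1e-14:
                # Secant acceleration of the scalar fixed point; fall back to
                # damped substitution if the step is wild.
                v_next = v_end - f_cur * (v_end - v_old) / (f_cur - f_old)
                if not (0.0 < v_next and abs(v_next - v_end) < 0.3 * v_end + 10.0):
                    v_next = None
            if v_next is None:
                v_next = v_end + config.relaxation * f_cur
            v_old, f_old = v_end, f_cur
            v_end = v_next
        if not converged:
            raise ConvergenceError(
                f"inner coupling iteration did not converge at t={t[k]:.4f} s "
                f"after {config.max_inner_iter} iterations",
                residual_history=history,
            )
        iters[k - 1] = i
        v_prev_step = state.cavity_volume
        state = replace(new_state, fiber_stretch=fiber_stretch(v_new, geometry))
        s_state = s_try
        record(k, state, ten, s_state)

    edv_per_cycle = np.array(
        [
            rec["volume"][c * steps_per_cycle : (c + 1) * steps_per_cycle + 1].max()
            for c in range(config.n_cycles)
        ]
    )
    if config.n_cycles >= 2:
        periodic = (
            abs(edv_per_cycle[-1] - edv_per_cycle[-2]) / edv_per_cycle[-2]
            < config.periodic_edv_tol
        )
    else:
        periodic = False

    return SimulationResult(
        time=t,
        volume=rec["volume"],
        p_lv=rec["p_lv"],
        p_ao=rec["p_ao"],
        q_mitral=rec["q_mitral"],
        q_aortic=rec["q_aortic"],
        stretch=rec["stretch"],
        tension=rec["tension"],
        stiffness=rec["stiffness"],
        frac_parked=rec["fp"],
        frac_detached=rec["fd"],
        frac_attached=rec["fa"],
        distortion=rec["dist"],
        inner_iterations=iters,
        steps_per_cycle=steps_per_cycle,
        periodic=periodic,
        edv_per_cycle=edv_per_cycle,
        config=config,
    )


@dataclass
class DrugComparison:
    """Paired baseline/treated runs with P-V metric deltas."""

    baseline: SimulationResult
    treated: SimulationResult
    baseline_metrics: PVMetrics
    treated_metrics: PVMetrics
    shift: LoopShift


def run_drug_comparison(
    calcium: CalciumTransient,
    kinetics: KineticParams,
    geometry: LVGeometry,
    circulation: CirculationParams,
    drug: CalciumDrugSpec | KineticDrugSpec,
    config: CouplingConfig = CouplingConfig(),
) -> DrugComparison:
    """Run identical configurations without and with a drug applied.

    The drug acts at its class-specific hook: a calcium drug rescales the
    transient, a kinetic drug rescales the crossbridge transition rates.
    Everything else is held fixed.
    """
    if isinstance(drug, CalciumDrugSpec):
        calcium_rx, kinetics_rx = apply_calcium_drug(calcium, drug), kinetics
    elif isinstance(drug, KineticDrugSpec):
        calcium_rx, kinetics_rx = calcium, apply_kinetic_drug(kinetics, drug)
    else:
        raise ParameterError(
            f"drug must be a CalciumDrugSpec or KineticDrugSpec, got {type(drug)}"
        )
    baseline = run_cycle(calcium, kinetics, geometry, circulation, config)
    treated = run_cycle(calcium_rx, kinetics_rx, geometry, circulation, config)
    mb = pv_metrics(baseline)
    mt = pv_metrics(treated)
    return DrugComparison(
        baseline=baseline,
        treated=treated,
        baseline_metrics=mb,
        treated_metrics=mt,
        shift=loop_shift(mb, mt),
    )
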