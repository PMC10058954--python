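"""Shared fixtures: phenotype specs, coupled baseline runs, twitch pairs.

The coupled runs are session-scoped because they are the expensive
objects every downstream metric test reuses.
"""

import time

import numpy as np
import pytest

import myoloop as ml
from myoloop import fe_flow as ff


@pytest.fixture(scope="session")
def hcm():
    return ml.generate_phenotype("hcm")


@pytest.fixture(scope="session")
def dcm():
    return ml.generate_phenotype("dcm")


def _timed_run(spec):
    t0 = time.perf_counter()
    res = ml.run_cycle(spec.calcium, spec.kinetics, spec.geometry, spec.circulation)
    return res, time.perf_counter() - t0


@pytest.fixture(scope="session")
def hcm_run(hcm):
    """Baseline HCM coupled run plus its wall-clock time in seconds."""
    return _timed_run(hcm)


@pytest.fixture(scope="session")
def dcm_run(dcm):
    return _timed_run(dcm)


@pytest.fixture(scope="session")
def hcm_twitch(hcm):
    """No-drug isometric twitch of the HCM phenotype."""
    return ml.simulate_twitch(ml.twitch_transient(hcm), hcm.kinetics)


@pytest.fixture(scope="session")
def disopyramide_twitch(hcm):
    """HCM twitch under the committed Disopyramide 5 µmol/L calibration."""
    drug = ml.dose_to_scales("disopyramide", 5.0)
    transient = ml.apply_calcium_drug(ml.twitch_transient(hcm), drug)
    return ml.simulate_twitch(transient, hcm.kinetics)


@pytest.fixture(scope="session")
def mavacamten_twitch(hcm):
    """HCM twitch under the committed Mavacamten 1 µmol/L calibration."""
    drug = ml.kinetic_dose_to_scales("mavacamten", 1.0)
    kinetics = ml.apply_kinetic_drug(hcm.kinetics, drug)
    return ml.simulate_twitch(ml.twitch_transient(hcm), kinetics)


def _treated_run(spec, drug):
    if isinstance(drug, ml.CalciumDrugSpec):
        return ml.run_cycle(
            ml.apply_calcium_drug(spec.calcium, drug),
            spec.kinetics,
            spec.geometry,
            spec.circulation,
        )
    return ml.run_cycle(
        spec.calcium,
        ml.apply_kinetic_drug(spec.kinetics, drug),
        spec.geometry,
        spec.circulation,
    )


@pytest.fixture(scope="session")
def hcm_drug_shifts(hcm, hcm_run):
    """Loop shifts of the two HCM drugs against the shared baseline."""
    base_metrics = ml.pv_metrics(hcm_run[0])
    shifts = {}
    for drug in (
        ml.dose_to_scales("disopyramide", 5.0),
        ml.kinetic_dose_to_scales("mavacamten", 1.0),
    ):
        treated = _treated_run(hcm, drug)
        shifts[drug.name] = ml.loop_shift(base_metrics, ml.pv_metrics(treated))
    return shifts


@pytest.fixture(scope="session")
def dcm_drug_shifts(dcm, dcm_run):
    base_metrics = ml.pv_metrics(dcm_run[0])
    shifts = {}
    for drug in (
        ml.dose_to_scales("digoxin", 1.0),
        ml.kinetic_dose_to_scales("datp", 1.0),
    ):
        treated = _treated_run(dcm, drug)
        shifts[drug.name] = ml.loop_shift(base_metrics, ml.pv_metrics(treated))
    return shifts


# ----- FE flow fixtures -----------------------------------------------------

CHANNEL_LENGTH = 1.0
CHANNEL_HEIGHT = 0.2
MEAN_VELOCITY = 1.0


def poiseuille_profile(x, y):
    h = CHANNEL_HEIGHT
    return 6.0 * MEAN_VELOCITY * y * (h - y) / h**2


def channel_bcs(mesh):
    bc = ff.BoundaryConditions()
    bc.set_velocity(mesh, "left", vx=poiseuille_profile, vy=0.0)
    bc.set_velocity(mesh, "bottom", vx=0.0, vy=0.0)
    bc.set_velocity(mesh, "top", vx=0.0, vy=0.0)
    return bc


@pytest.fixture(scope="session")
def poiseuille_solution():
    """Converged plane-channel solve on the 20x8 mesh (mu=1, rho=1)."""
    mesh = ff.rect_mesh(20, 8, CHANNEL_LENGTH, CHANNEL_HEIGHT)
    system = ff.FESystem(mesh, ff.FluidProperties(1.0, 1.0))
    v, p, iters = ff.solve_time_step(system, channel_bcs(mesh), tol=1e-12)
    return mesh, system, v, p
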