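"""Crossbridge surrogate: kinetics, conservation, tension and drug hooks."""

import numpy as np
import pytest
from scipy.linalg import null_space

import myoloop as ml
from myoloop.calcium import CalciumTransient
from myoloop.errors import ParameterError, StepSizeError
from myoloop.sarcomere import (
    SarcomereState,
    rate_matrix,
    steady_state,
    step_state,
)


def params(**kw):
    base = dict(
        k_off_to_on=0.3,
        k_on_to_off=0.3,
        k_attach=40.0,
        k_detach=20.0,
        detach_strain_sensitivity=0.3,
        t_max=120.0,
        ca50=0.5,
        hill_h=4.0,
        overlap_width=0.6,
        stiffness_per_attached=2000.0,
    )
    base.update(kw)
    return ml.KineticParams(**base)


class TestActivation:
    def test_hill_midpoint_is_half(self):
        assert ml.thin_filament_activation(0.5, 1.0, params()) == pytest.approx(0.5)

    def test_saturates_at_high_calcium(self):
        assert ml.thin_filament_activation(1e6, 1.0, params()) == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_hill_expression(self):
        # independently coded: ca^h / (ca50^h + ca^h) at stretch 1
        expected = 0.3**4 / (0.5**4 + 0.3**4)
        assert ml.thin_filament_activation(0.3, 1.0, params()) == pytest.approx(
            expected, rel=1e-12
        )

    def test_longer_sarcomere_is_more_sensitive(self):
        p = params()
        assert ml.thin_filament_activation(0.4, 1.1, p) > ml.thin_filament_activation(
            0.4, 1.0, p
        )


class TestStateStepping:
    def test_vanishing_rates_freeze_the_state(self):
        p = params(k_off_to_on=1e-12, k_on_to_off=1e-12, k_attach=1e-12, k_detach=1e-12)
        s0 = SarcomereState(0.3, 0.5, 0.2)
        s1 = step_state(s0, 1.0, 1.0, 0.0, 1e-3, p)
        assert s1.fractions == pytest.approx(s0.fractions, abs=1e-12)

    def test_fractions_conserved_over_many_random_steps(self):
        """Population is conserved across 1e5 randomly driven steps."""
        rng = np.random.default_rng(42)
        p = params()
        s = steady_state(0.2, 1.0, p)
        worst = 0.0
        for _ in range(100_000):
            s = step_state(
                s,
                ca=rng.uniform(0.0, 2.0),
                stretch=rng.uniform(0.8, 1.2),
                stretch_rate=rng.uniform(-1.0, 1.0),
                dt=rng.uniform(1e-4, 2e-3),
                params=p,
            )
            worst = max(worst, abs(s.fractions.sum() - 1.0))
        assert worst < 1e-10

    def test_dynamics_converge_to_rate_matrix_null_space(self):
        """Long integration at constant drive lands on the algebraic fixed
        point computed by an independent dense null-space solve."""
        p = params(k_off_to_on=2.0, k_on_to_off=2.0)
        ca, stretch = 0.6, 1.0
        s = SarcomereState(1.0, 0.0, 0.0)
        t_end = 8.0  # several multiples of the slowest relaxation time
        n = int(t_end / 1e-3)
        for _ in range(n):
            s = step_state(s, ca, stretch, 0.0, 1e-3, p)
        q = rate_matrix(ca, stretch, p)
        ns = null_space(q)
        assert ns.shape[1] == 1
        expected = ns[:, 0] / ns[:, 0].sum()
        assert np.linalg.norm(s.fractions - expected) / np.linalg.norm(expected) < 1e-3

    def test_huge_step_is_rejected(self):
        with pytest.raises(StepSizeError):
            step_state(SarcomereState(0.5, 0.3, 0.2), 1.0, 1.0, 0.0, 1.0, params())

    def test_invalid_fractions_are_rejected(self):
        with pytest.raises(ParameterError):
            SarcomereState(0.9, 0.9, 0.9)


class TestTension:
    def test_no_attached_bridges_no_tension(self):
        res = ml.active_tension(SarcomereState(0.5, 0.5, 0.0), 1.0, params())
        assert res.active_tension == 0.0 and res.instantaneous_stiffness == 0.0

    def test_tension_linear_in_attached_fraction(self):
        p = params()
        t1 = ml.active_tension(SarcomereState(0.8, 0.1, 0.1), 1.0, p).active_tension
        t2 = ml.active_tension(SarcomereState(0.6, 0.1, 0.3), 1.0, p).active_tension
        assert t2 == pytest.approx(3 * t1, rel=1e-12)

    def test_quarter_attached_at_optimal_overlap(self):
        # stretch at the overlap optimum and zero distortion: T = t_max/4
        res = ml.active_tension(SarcomereState(0.5, 0.25, 0.25), 1.05, params())
        assert res.active_tension == pytest.approx(30.0, rel=1e-12)

    def test_steady_tension_zero_without_calcium(self):
        assert ml.steady_state_tension(0.0, 1.0, params()) == 0.0

    def test_steady_tension_monotone_in_calcium(self):
        p = params()
        grid = np.linspace(0.0, 3.0, 16)
        vals = [ml.steady_state_tension(c, 1.0, p) for c in grid]
        assert np.all(np.diff(vals) >= -1e-12)


class TestKineticDrugs:
    def test_identity_scales_change_nothing(self):
        p = params()
        assert ml.apply_kinetic_drug(p, ml.KineticDrugSpec("none", 0.0)) == p

    def test_parked_state_stabiliser_increases_srx_occupancy(self):
        # Mavacamten-like OFF->ON inhibition grows the parked fraction
        p = params()
        rx = ml.apply_kinetic_drug(p, ml.KineticDrugSpec("mava", 1.0, scale_off_to_on=0.4))
        assert steady_state(1.0, 1.0, rx).frac_parked > steady_state(1.0, 1.0, p).frac_parked

    def test_attachment_enhancer_raises_saturating_tension(self):
        """dATP-like attachment boost raises the fixed-point tension,
        cross-checked against the dense null-space oracle."""
        p = params()
        rx = ml.apply_kinetic_drug(p, ml.KineticDrugSpec("datp", 1.0, scale_attach=1.5))
        base = ml.steady_state_tension(10.0, 1.0, p)
        boosted = ml.steady_state_tension(10.0, 1.0, rx)
        assert boosted > base
        ns = null_space(rate_matrix(10.0, 1.0, rx))
        frac_attached = (ns[:, 0] / ns[:, 0].sum())[2]
        oracle = rx.t_max * frac_attached * (1 - ((1.0 - 1.05) / rx.overlap_width) ** 2)
        assert boosted == pytest.approx(oracle, rel=1e-9)

    def test_mavacamten_calibration_hits_steady_state_force_drop(self, hcm):
        """~30% decrease of steady-state force at saturating calcium."""
        drug = ml.kinetic_dose_to_scales("mavacamten", 1.0)
        rx = ml.apply_kinetic_drug(hcm.kinetics, drug)
        drop = 100 * (
            1 - ml.steady_state_tension(10.0, 1.0, rx) / ml.steady_state_tension(10.0, 1.0, hcm.kinetics)
        )
        assert drop == pytest.approx(30.0, abs=3.0)

    def test_mavacamten_lowers_resting_tension(self, hcm_twitch, mavacamten_twitch):
        assert mavacamten_twitch.resting_tension < hcm_twitch.resting_tension


class TestTwitch:
    def test_zero_calcium_means_zero_tension(self):
        tr = CalciumTransient(0.0, 1e-9, 0.05, 0.02, 0.15)
        res = ml.simulate_twitch(tr, params())
        assert np.all(res.tension < 1e-9)

    def test_clamped_calcium_reaches_steady_state_tension(self):
        """A calcium step held for the whole cycle drives the twitch onto
        the algebraic steady state within 1%."""
        p = params(k_off_to_on=2.0, k_on_to_off=2.0)
        ca = 0.8
        s = steady_state(0.0, 1.0, p)
        for _ in range(3000):
            s = step_state(s, ca, 1.0, 0.0, 1e-3, p)
        late = ml.active_tension(s, 1.0, p).active_tension
        assert late == pytest.approx(ml.steady_state_tension(ca, 1.0, p), rel=1e-2)

    def test_twitch_reports_peak_and_timing(self, hcm_twitch):
        assert hcm_twitch.peak_tension > hcm_twitch.resting_tension > 0
        assert 0.0 < hcm_twitch.time_to_peak < 1.0

    @pytest.mark.parametrize(
        "drug_name,kind,sign",
        [("mavacamten", "kinetic", -1), ("digoxin", "calcium", 1)],
    )
    def test_peak_twitch_tension_monotone_in_dose(self, hcm, drug_name, kind, sign):
        tw = ml.twitch_transient(hcm)
        peaks = []
        for dose in (0.0, 0.3, 1.0, 3.0):
            if kind == "kinetic":
                kin = ml.apply_kinetic_drug(hcm.kinetics, ml.kinetic_dose_to_scales(drug_name, dose))
                peaks.append(ml.simulate_twitch(tw, kin).peak_tension)
            else:
                tr = ml.apply_calcium_drug(tw, ml.dose_to_scales(drug_name, dose))
                peaks.append(ml.simulate_twitch(tr, hcm.kinetics).peak_tension)
        assert np.all(sign * np.diff(peaks) > 0)

    def test_peak_tension_monotone_in_attachment_enhancement(self, hcm):
        tw = ml.twitch_transient(hcm)
        peaks = [
            ml.simulate_twitch(
                tw,
                ml.apply_kinetic_drug(
                    hcm.kinetics, ml.KineticDrugSpec("datp", 1.0, scale_attach=s)
                ),
            ).peak_tension
            for s in (1.0, 1.2, 1.5)
        ]
        assert np.all(np.diff(peaks) > 0)
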