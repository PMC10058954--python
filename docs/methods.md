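# Methods

This note documents the model, its numerical treatment, the provenance of
every tunable default, and what the synthetic study conditions do and do not
establish.

## 1. Calcium transient

The twitch transient is a double exponential with an onset latency,

    ca(t) = ca_base                                   t < t0
    ca(t) = ca_base + A (e^{-(t-t0)/τ_d} − e^{-(t-t0)/τ_r})   t ≥ t0

with `A` set analytically so the maximum equals `ca_peak`, and
`t0 = t_peak − t*`, where `t* = τ_r τ_d/(τ_d − τ_r) · ln(τ_d/τ_r)` is the
intrinsic peak location. Parameter sets whose time constants would place the
intrinsic peak after the requested `t_peak` are rejected (a negative latency
would violate `ca(0) = ca_base`). The latency plays a second role: chamber
phenotypes use `t_peak = 0.55 s` so the first half of the 1-s cycle is
diastole and systole peaks late, matching the displayed timing of a cardiac
cycle, while twitch experiments re-time the same transient to
`t_peak = 0.05 s` (`scenarios.twitch_transient`).

Units are µmol/L and seconds. The numeric amplitudes (HCM: base 0.14, peak
1.0; DCM: base 0.12, peak 0.75) are implementer calibration values — no
published table of transient amplitudes exists for these phenotypes — and
are marked as such in `defaults.yaml`. The mildly elevated HCM basal calcium
is deliberate: it produces the diastolic active tension (diastolic
dysfunction) that lets negative inotropes improve filling, which is what
moves the HCM loop toward higher volumes under treatment.

## 2. Crossbridge surrogate

Three myosin populations — parked (OFF/SRX), detached (ON/DRX), attached —
evolve by master equations with generator

    parked  ⇄  detached        k_off_to_on / k_on_to_off
    detached → attached        k_attach · act(ca, λ)
    attached → detached        k_detach · min(e^{σ|x|}, 10)

`act` is Hill activation `(ca/ca50_eff)^h / (1 + (ca/ca50_eff)^h)` with a
length-dependent half-point `ca50_eff = ca50 · max(1 − (λ − 1), 0.2)`
(longer sarcomeres are more calcium-sensitive). The scalar distortion `x`
(nm, 0 at isometric steady state) relaxes at the effective detach rate
toward a stretch-rate-driven target `x_t = 2 nm·s · dλ/dt`; tension is

    T = T_max · f_attached · overlap(λ) · max(0, 1 + x/5 nm)

with `overlap(λ) = max(0, 1 − ((λ − 1.05)/w)²)`. Shortening during ejection
(dλ/dt ≈ −0.5/s) therefore depresses force by ~20% — a deliberate, mild
force–velocity effect — and strained bridges detach faster, with the strain
amplification capped at 10× so extreme transients cannot blow up the detach
rate. Instantaneous stiffness is reported as
`stiffness_per_attached · f_attached` and is used only for coupling
diagnostics, not fed back into wall mechanics.

This is the minimal structure that exposes every drug hook the two trial
scenarios need (OFF/ON transition rates, attach/detach cycling, the calcium
transient). It does not resolve the filament lattice, does not sample
stochastic crossbridges, and makes no claim of re-implementing a
molecular-scale platform.

Default rates (all chosen, not fitted): `k_off_to_on = k_on_to_off =
0.3 /s` — the parked pool exchanges on a seconds timescale, so roughly half
the heads are parked at diastole and the pool barely re-equilibrates within
one twitch, which is what makes an SRX-stabilising drug effective;
`k_attach = 40 /s`, `k_detach = 20 /s` give an attached duty ratio ~2/3 of
the available heads at saturating calcium; `h = 4` is standard
thin-filament cooperativity; `ca50 = 0.5 µmol/L`.

### Drug calibration (scripts/calibrate.py, run once, values frozen)

* **Disopyramide** (calcium class): scale factors on (peak, base) fitted by
  alternating scalar root-finds so the HCM isometric twitch shows a 55%
  peak-tension and 50% resting-tension reduction at the 5 µmol/L
  calibration dose → committed saturation scales (0.2737, 0.8257) with a
  chosen EC50 of 1 µmol/L and Hill-1 dose–response.
* **Mavacamten** (kinetic class): the OFF→ON rate scale fitted so
  steady-state tension at saturating calcium falls 30% at 1 µmol/L →
  committed saturation scale 0.1789 (EC50 0.3 µmol/L). The same
  calibration then *predicts* a 46% twitch-peak reduction and a 46% resting
  tension reduction — consistent with the ~50% twitch effect expected of
  the drug, and a genuine cross-check because the twitch was not fitted.
* **Digoxin / dATP**: only direction and rough magnitude are constrained by
  the literature ("up to twofold" twitch-tension gain for Digoxin; ~1%
  dATP substitution already effective), so their saturation scales are
  chosen, not calibrated: Digoxin saturates at 2× peak calcium with
  timing untouched; dATP at 1.6× attachment and 1.4× OFF→ON.

## 3. Chamber, valves and afterload

The ventricle is a thick-wall Laplace chamber: equivalent cavity radius
`r(V)` (sphere, or equatorial radius of a half prolate spheroid with
elongation 1.8 for the truncated-ellipsoid shape), fiber stretch
`λ = (V/V0)^{1/3}`, active cavity pressure `P = 2 T h / r` (kPa → mmHg via
7.50062), passive EDPVR `p0 (e^{k(V−V0)} − 1)` with a C¹ linear
continuation below `V0`. Valves are ideal diodes with series resistances;
the afterload is a three-element Windkessel (`Zc`, `Rp`, `C`) whose
compliance-node pressure is the state variable; the proximal arterial
pressure is `P_wk + Zc Q`. Constant inflow settles exactly on
`P = Q (Zc + Rp)`.

Per-phenotype `T_max` is the *chamber-level* contractility calibration
constant, fitted by bisection so the no-drug models reproduce their
baseline ejection fractions (HCM 78.4 kPa → LVEF 59.33%; DCM 192 kPa →
LVEF 56.83%). The DCM value is larger than the HCM one even though DCM is
the hypocontractile disease: a dilated thin-walled chamber is at a severe
Laplace disadvantage (`h/r` small), so a higher fiber tension is needed for
a lower cavity pressure. `T_max` absorbs everything the reduced geometry
cannot represent; drug percentage effects are ratios and therefore
independent of it. The remaining circulation constants are chosen for
physiological plausibility (DCM gets a low characteristic impedance and a
vasodilated periphery, consistent with its larger stroke volume at lower
pressure) and marked `chosen`/`calibrated` individually in
`defaults.yaml`.

## 4. Loose coupling

Within each 1-ms step: propose an end-of-step volume (linear extrapolation
as initial guess) → stretch and stretch rate → sarcomere step → tension →
cavity pressure → valve flows → new volume. The scalar fixed point is
accelerated by a secant update (safeguarded; damped substitution with
factor 0.5 as fallback), and convergence requires the relative changes of
active tension *and* aortic outflow velocity to fall below 1e-4 (absolute
floors 1e-3 kPa and 1e-3 cm/s prevent stalling in zero-flow phases).
Typical cost is 2–3 inner iterations per step; hitting the 50-iteration cap
raises a structured error carrying the residual history. Ten cycles are run
by default; periodicity is flagged when the cycle-to-cycle EDV change drops
below 0.5% (the final cycle then closes to ≲0.01 mL). The state update
uses the exact matrix exponential of the frozen 3-state generator
(unconditionally conservative — fractions sum to 1 to machine precision)
with the distortion relaxed exponentially; both are exact for frozen
coefficients, so 1 ms comfortably resolves every rate in the model.

The pipeline is deterministic: reruns are bitwise identical, and the seed
only enters virtual-patient jitter, never the solver.

## 5. FE flow kernel

The 2-D kernel implements the incremental-iterative mixed formulation:
Taylor–Hood Q2/Q1 quadrilaterals (inf-sup stable; the element pair is an
implementation choice), consistent mass `ρ∫NᵀN`, viscous stiffness in
gradient form `μ∫∇N:∇N`, convection lagged at the previous Picard iterate,
discrete divergence blocks with the exact transpose relation, backward
Euler in time, and direct sparse solves of the saddle-point system with
row/column elimination of Dirichlet dofs (one pressure node pinned when no
traction boundary exists). Boundary reaction forces — the vector handed to
a structure in loose coupling — are the momentum operator applied to the
converged `(V, P)` restricted to the tagged nodes.

Verification: plane Poiseuille flow is in the discrete space on undistorted
meshes (centerline `1.5 U_mean` to machine precision, divergence residual
~1e-15); wall drag matches `6 μ U/h` within 5% on a 20×8 mesh (corner
nodes shared with the inlet account for the discrepancy); on smoothly
curved meshes (an interior sine remap that leaves the domain unchanged) the
error is finite and falls at high order under refinement, which is the
meaningful convergence test for a Q2 discretisation of a quadratic
solution. The kernel is verified standalone and is not inserted into the
chamber loop — the lumped chamber plays the fluid role there by design.
3-D assembly, ALE mesh motion and monolithic coupling are out of scope.

## 6. Virtual patients and waveforms

`generate_phenotype(label, seed, jitter)` perturbs geometry (V0, wall,
valve diameters), contractile rates (`k_attach`, `k_detach`, `T_max`) and
calcium amplitude multiplicatively, uniform in `[1−j, 1+j]`, `j ≤ 0.3`,
from a generator seeded by `seed`; `j = 0` returns the committed defaults
exactly. Valve velocity waveforms are raised-cosine pulses in disjoint
diastolic/systolic windows, with amplitudes scaled proportionally to the
mitral (inlet) and aortic (outlet) valve diameters; their shapes and
nominal peaks (60 and 100 cm/s) are implementer choices, since only the
scaling rule is specified by the physiology.

What the synthetic conditions demonstrate — and what they do not: the
pipeline reproduces the calibrated fiber-level drug effects end-to-end, the
baseline ejection fractions, and the qualitative loop-shift directions of
all four drugs, robustly across ±10% parameter jitter. They do not
establish patient-specific accuracy: geometries are lumped, the wall
material is a two-parameter EDPVR, atrial and outflow-tract dynamics are
absent, and calcium amplitudes are calibration constants. One caveat is
worth stating explicitly: under negative inotropes the model's HCM
ejection fraction falls (stroke volume grows less than EDV), whereas
clinically an HCM LVEF rise is reported; capturing that would require
outflow-tract obstruction relief, which this geometry does not represent.
The asserted treatment directions are therefore the pressure and volume
shifts, which the reduced model does capture.

## 7. Numerical conventions and degenerate inputs

* Units: mmHg/mL/s/cm externally, kPa for tension; single conversion
  constant in `myoloop.units`.
* Time grid: fixed 1 ms step, cycle length 1.0 s.
* Renormalisation: state fractions are clipped at 0 and renormalised after
  each exponential step; clipping beyond 1e-8 warns, beyond 1e-6 raises a
  step-size error (with the exponential update neither normally triggers).
* Degenerate inputs: zero calcium yields identically zero tension and a
  passive-filling P-V trajectory; a drug spec that scales the calcium peak
  below the base raises a contradiction error; inverted mesh elements are
  reported by element id; an over-large sarcomere step is rejected with
  advice to reduce `dt`.
* EDV/ESV are the extrema of the final cycle (robust to timing
  conventions); stroke work is the shoelace area of the closed loop,
  positive for an ejecting cycle; LVEF is printed to two decimals.

## 8. Problem sizes

Default runs use 1000 steps/cycle × 10 cycles for chamber simulations
(~1 s wall time each), 1001-step twitches, and FE meshes up to 20×8
elements (~1700 dofs) — sizes chosen so every shipped scenario completes in
seconds on one CPU while keeping all discretisation errors far below the
tolerances asserted in the tests.
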