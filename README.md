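# myoloop

Desk-scale multiscale simulation of left-ventricular (LV) contraction for
in-silico drug trials on cardiomyopathy phenotypes.

Hypertrophic cardiomyopathy (HCM, thick wall and small cavity) and dilated
cardiomyopathy (DCM, thin wall and enlarged cavity) change both the
contractile machinery and chamber mechanics of the heart, and the drugs used
to treat them act at the molecular scale — on the intracellular calcium
transient (Disopyramide, Digoxin) or on myosin crossbridge kinetics
(Mavacamten, dATP). `myoloop` links those scales in a single deterministic
pipeline so that a dose entered at the sarcomere level comes out as a shift
of the pressure–volume (P-V) loop and the ejection fraction at the chamber
level. It is aimed at computational physiologists who want a transparent,
fully scriptable surrogate of this chain rather than a patient-specific 3-D
finite-element model.

## The model

* **Calcium drive.** A parametric twitch transient
  `ca(t) = ca_base + A (e^{-t/τ_d} − e^{-t/τ_r})`, with the amplitude `A`
  fixed analytically so the maximum equals `ca_peak` at `t_peak`.
  Scenario-1 drugs rescale `ca_peak`/`ca_base` (and optionally the time
  constants) through a saturating Hill dose–response.
* **Sarcomere surrogate.** Myosin heads occupy three states — parked
  (OFF/SRX), detached (ON/DRX) and attached — exchanging by first-order
  master equations; calcium enters through Hill thin-filament activation
  with length-dependent sensitivity, and a scalar distortion variable
  carries the force–velocity effect. Active tension is
  `T = T_max · f_attached · overlap(λ) · distortion factor`. Scenario-2
  drugs multiply the four transition rates.
* **Chamber and circulation.** Thick-wall Laplace mechanics,
  `P_active = 2 T h / r`, an exponential passive end-diastolic
  pressure–volume relation, diode mitral/aortic valves and a three-element
  Windkessel afterload. `LVEF = 100 · (EDV − ESV)/EDV`.
* **Loose coupling.** Per time step the chamber proposes a volume (hence a
  fiber stretch), the sarcomere returns tension and stiffness, and the
  circulation updates the volume; the exchange iterates (secant-accelerated
  fixed point) until the relative changes of tension and outflow velocity
  drop below tolerance — the same partitioned structure used in
  fluid–structure interaction.
* **FE flow kernel** (`myoloop.fe_flow`). A miniature 2-D mixed
  velocity–pressure solver for incompressible Navier–Stokes: Taylor–Hood
  quadrilaterals, consistent mass `ρNᵀN`, Picard-lagged convection,
  backward-Euler stepping and nodal boundary-force extraction — the fluid
  side of the loose-coupling scheme, verified standalone against plane
  Poiseuille flow.

## Worked example

```python
import myoloop as ml

spec = ml.generate_phenotype("hcm")          # committed HCM defaults
result = ml.run_cycle(spec.calcium, spec.kinetics,
                      spec.geometry, spec.circulation)
print(ml.pv_metrics(result))
```

Running `python examples/pv_loop_baselines.py` prints

```
HCM: EDV   66.7 mL  ESV   27.1 mL  LVEF 59.33%  peak P  122.6 mmHg  stroke work    3744 mmHg*mL  (periodic=True, mean inner iters 2.5)
DCM: EDV  162.4 mL  ESV   70.1 mL  LVEF 56.84%  peak P   99.6 mmHg  stroke work    6822 mmHg*mL  (periodic=True, mean inner iters 2.5)
```

— the small, high-pressure HCM ventricle and the dilated, low-pressure DCM
ventricle both eject a mildly reduced fraction of their end-diastolic
volume. `examples/twitch_drug_effects.py` shows the fiber-level drug
calibrations (Disopyramide 5 µmol/L: peak twitch tension −55%, resting
tension −50%; Mavacamten 1 µmol/L: steady-state force −30%, twitch peak
−46%), and `examples/drug_trial_comparison.py` runs the four drug trials,
printing the loop shifts (HCM drugs: pressure down, loop toward higher
volumes; DCM drugs: pressure up, loop toward lower volumes). The other
examples exercise the FE kernel and the virtual-patient generator.

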