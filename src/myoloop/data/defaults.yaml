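# Default configuration for myoloop.
#
# Provenance key used throughout:
#   calibrated — fitted once (scripts/calibrate.py) against a published headline
#                effect (drug percentage effects, baseline ejection fractions)
#                and then frozen; regression tests reproduce the number
#                end-to-end from these values.
#   chosen     — implementer default; no published number exists for it.

time:
  dt_s: 0.001            # chosen: 1 ms step resolves every rate in the model
  cycle_length_s: 1.0    # chosen: 1 s cycle, matching the displayed cardiac cycle

# ---------------------------------------------------------------------------
# Drug registry. Dose-response is Hill with coefficient 1:
#   scale(dose) = 1 + (sat - 1) * dose / (ec50 + dose)
# so dose 0 -> 1 and dose -> inf -> sat. "calibration" records the scale
# factors obtained at the calibration dose; tests assert consistency.
# ---------------------------------------------------------------------------
calcium_drugs:
  disopyramide:
    ec50_umol_per_l: 1.0          # chosen
    sat_scale_peak: 0.2737        # calibrated: ~55% peak twitch tension drop at 5 umol/L
    sat_scale_base: 0.8257        # calibrated: ~50% resting tension drop at 5 umol/L
    sat_scale_times: 1.0          # chosen: no reported effect on twitch timing
    calibration_dose_umol_per_l: 5.0
  digoxin:
    ec50_umol_per_l: 0.5          # chosen
    sat_scale_peak: 2.0           # chosen: saturating peak-calcium gain giving up to ~2x twitch tension
    sat_scale_base: 1.0           # fixed: diastolic calcium unchanged
    sat_scale_times: 1.0          # fixed: time-to-peak and relaxation unchanged
    calibration_dose_umol_per_l: 1.0

kinetic_drugs:
  mavacamten:
    ec50_umol_per_l: 0.3          # chosen
    sat_scale_off_to_on: 0.1789   # calibrated: ~30% steady-state force drop at 1 umol/L
    sat_scale_on_to_off: 1.0      # chosen: effect carried by the ON<-OFF forward rate
    sat_scale_attach: 1.0
    sat_scale_detach: 1.0
    calibration_dose_umol_per_l: 1.0
  datp:
    # dose expressed as percent of the ATP pool replaced by dATP
    ec50_pct: 0.5                 # chosen: ~1% substitution already near-saturating
    sat_scale_off_to_on: 1.4      # chosen: destabilises the parked state
    sat_scale_on_to_off: 1.0
    sat_scale_attach: 1.6         # chosen: enhanced crossbridge binding/cycling
    sat_scale_detach: 1.0
    calibration_dose_pct: 1.0

# ---------------------------------------------------------------------------
# Phenotypes. Geometry in cm/mL, pressures mmHg, tensions kPa, times s.
# ---------------------------------------------------------------------------
phenotypes:
  hcm:
    geometry:
      cavity_ref_volume_ml: 45.0   # calibrated: small cavity
      wall_thickness_cm: 1.6       # chosen: hypertrophied wall
      mitral_diameter_cm: 2.3      # chosen
      aortic_diameter_cm: 2.0      # chosen
      shape: sphere
    calcium:
      ca_base_umol_per_l: 0.14     # chosen: mildly elevated diastolic calcium (diastolic dysfunction)
      ca_peak_umol_per_l: 1.0      # chosen
      t_peak_s: 0.55               # chosen: systole late in the cycle (diastole first)
      tau_rise_s: 0.02             # chosen
      tau_decay_s: 0.15            # chosen
    kinetics:
      k_off_to_on_per_s: 0.3       # chosen: slow parked<->available exchange
      k_on_to_off_per_s: 0.3       # chosen: ~50% parked at diastole
      k_attach_per_s: 40.0         # chosen
      k_detach_per_s: 20.0         # chosen
      detach_strain_sensitivity_per_nm: 0.3   # chosen
      t_max_kpa: 78.4              # calibrated: chamber contractility -> baseline ejection fraction
      ca50_umol_per_l: 0.5         # chosen
      hill_h: 4.0                  # chosen: thin-filament cooperativity
      overlap_width: 0.6           # chosen
      stiffness_per_attached_kpa: 2000.0      # chosen
    circulation:
      atrial_pressure_mmhg: 10.0   # chosen
      mitral_resistance: 0.05      # chosen, mmHg*s/mL
      aortic_resistance: 0.08      # chosen, mmHg*s/mL (characteristic impedance)
      peripheral_resistance: 2.0   # calibrated
      arterial_compliance: 1.3     # chosen, mL/mmHg
      passive_p0_mmhg: 0.4         # chosen: EDPVR scale
      passive_k_per_ml: 0.06       # chosen: stiff small ventricle
  dcm:
    geometry:
      cavity_ref_volume_ml: 120.0  # calibrated: dilated cavity
      wall_thickness_cm: 0.9       # chosen: thinned wall
      mitral_diameter_cm: 2.8      # chosen
      aortic_diameter_cm: 2.2      # chosen
      shape: sphere
    calcium:
      ca_base_umol_per_l: 0.12     # chosen
      ca_peak_umol_per_l: 0.75     # chosen: blunted transient (reduced contractility)
      t_peak_s: 0.55
      tau_rise_s: 0.02
      tau_decay_s: 0.15
    kinetics:
      k_off_to_on_per_s: 0.3
      k_on_to_off_per_s: 0.3
      k_attach_per_s: 40.0
      k_detach_per_s: 20.0
      detach_strain_sensitivity_per_nm: 0.3
      t_max_kpa: 192.0             # calibrated: chamber contractility -> baseline ejection fraction
      ca50_umol_per_l: 0.5
      hill_h: 4.0
      overlap_width: 0.6
      stiffness_per_attached_kpa: 2000.0
    circulation:
      atrial_pressure_mmhg: 12.0   # chosen: congested left atrium
      mitral_resistance: 0.05
      aortic_resistance: 0.04      # calibrated: low characteristic impedance of the dilated outflow
      peripheral_resistance: 0.5   # calibrated: vasodilated periphery (heart-failure therapy baseline)
      arterial_compliance: 1.8     # chosen: compliant dilated arterial tree
      passive_p0_mmhg: 0.3         # chosen
      passive_k_per_ml: 0.05       # chosen: dilation is carried by the large V0
  normal:
    geometry:
      cavity_ref_volume_ml: 70.0   # chosen
      wall_thickness_cm: 1.1       # chosen
      mitral_diameter_cm: 2.5      # chosen
      aortic_diameter_cm: 2.1      # chosen
      shape: sphere
    calcium:
      ca_base_umol_per_l: 0.13
      ca_peak_umol_per_l: 1.0
      t_peak_s: 0.55
      tau_rise_s: 0.02
      tau_decay_s: 0.15
    kinetics:
      k_off_to_on_per_s: 0.3
      k_on_to_off_per_s: 0.3
      k_attach_per_s: 40.0
      k_detach_per_s: 20.0
      detach_strain_sensitivity_per_nm: 0.3
      t_max_kpa: 130.0             # chosen: normal-range ejection fraction (~58%)
      ca50_umol_per_l: 0.5
      hill_h: 4.0
      overlap_width: 0.6
      stiffness_per_attached_kpa: 2000.0
    circulation:
      atrial_pressure_mmhg: 10.0
      mitral_resistance: 0.05
      aortic_resistance: 0.08
      peripheral_resistance: 1.3
      arterial_compliance: 1.5
      passive_p0_mmhg: 0.3
      passive_k_per_ml: 0.05

# Nominal valve waveform amplitudes (scaled by valve diameter at run time).
waveforms:
  ref_mitral_diameter_cm: 2.5     # chosen
  ref_aortic_diameter_cm: 2.1     # chosen
  peak_inlet_velocity_cm_s: 60.0  # chosen: E-wave-like filling pulse
  peak_outlet_velocity_cm_s: 100.0  # chosen: systolic ejection pulse
  diastole_window_s: [0.05, 0.50] # chosen: filling occupies the first half-cycle
  systole_window_s: [0.55, 0.90]  # chosen

# Blood properties for the FE flow kernel (SI units).
fluid:
  dynamic_viscosity_pa_s: 0.0035  # chosen: blood
  density_kg_m3: 1050.0           # chosen: blood
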