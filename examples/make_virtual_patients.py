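"""Generate a cohort of jittered virtual patients and write one fixture.

Phenotype specs are deterministic in (label, seed, jitter): a 10%
multiplicative jitter around the committed HCM/DCM defaults emulates
between-patient variability in geometry, contractility and calcium
amplitude. One scenario directory (phenotype YAML + valve-velocity
waveform CSV, seed recorded in every header) is written under scratch/.
"""

from pathlib import Path

import myoloop as ml
from myoloop.scenarios import write_scenario_dir

print(f"{'label':6} {'seed':>4} {'V0 mL':>7} {'wall cm':>8} {'t_max kPa':>10}")
for label in ("hcm", "dcm"):
    for seed in range(3):
        s = ml.generate_phenotype(label, seed=seed, jitter=0.1)
        print(f"{s.label:6} {s.seed:4d} {s.geometry.cavity_ref_volume:7.1f} "
              f"{s.geometry.wall_thickness:8.2f} {s.kinetics.t_max:10.1f}")

out = write_scenario_dir(ml.generate_phenotype("hcm", seed=1, jitter=0.1),
                         Path("scratch") / "hcm_patient_1")
print(f"\nwrote scenario fixture to {out}/ (phenotype.yaml, waveforms.csv)")
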