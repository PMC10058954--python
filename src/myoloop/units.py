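"""Unit conversion constants.

External interfaces use clinical units (mmHg, mL, s, cm); tissue
mechanics is computed in kPa. All conversions go through this module so
there is a single authoritative constant for each factor.
"""

#: 1 kPa expressed in mmHg.
KPA_TO_MMHG = 7.50062

#: 1 mmHg expressed in kPa.
MMHG_TO_KPA = 1.0 / KPA_TO_MMHG


def kpa_to_mmhg(p_kpa: float) -> float:
    return p_kpa * KPA_TO_MMHG


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_KPA
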