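"""Unit conversion constants.

Public API works in clinical units (mmHg, mL, cm, m/s); the pulse solver
works in SI internally.
"""

MMHG_TO_PA = 133.322387415
ML_TO_M3 = 1e-6
CM_TO_M = 1e-2
CM2_TO_M2 = 1e-4

#: mmHg·s/mL -> Pa·s/m^3
RES_TO_SI = MMHG_TO_PA / ML_TO_M3
#: mL/mmHg -> m^3/Pa
CAP_TO_SI = ML_TO_M3 / MMHG_TO_PA


def dubois_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m²) by the DuBois formula."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725
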