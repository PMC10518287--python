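"""Unit conversions and physical constants.

SI units are used internally (m, s, Pa, mol/m^3). Experimental conventions
(minutes, molar, mmHg, mOsm) are converted at the interfaces: 1 M = 1000
mol/m^3 and 1 mOsm = 1 mol/m^3 (ideal, fully dissociated osmolarity).
"""

GAS_CONSTANT = 8.314  # J/(mol K)

MMHG_TO_PA = 133.322
MIN_TO_S = 60.0
MOLAR_TO_MOL_M3 = 1000.0  # 1 mol/L in mol/m^3
MOSM_TO_MOL_M3 = 1.0

ISOTONIC_OSMOLARITY = 290.0  # mol/m^3, mammalian isotonic reference


def molar(c_mol_m3: float) -> float:
    """mol/m^3 -> mol/L."""
    return c_mol_m3 / MOLAR_TO_MOL_M3


def mol_m3(c_molar: float) -> float:
    """mol/L -> mol/m^3."""
    return c_molar * MOLAR_TO_MOL_M3
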