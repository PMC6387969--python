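"""Physical constants and unit conversions.

Internal unit regime: volts, A·m⁻², S·m⁻², mol·m⁻³, seconds.
Interfaces speak mV and µM/mM; mM is numerically identical to mol·m⁻³.
"""

FARADAY = 96485.33212  # C mol^-1
GAS_CONSTANT = 8.31446  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 293.0  # K, room temperature

MV_PER_V = 1000.0
UM_PER_MOL_M3 = 1000.0  # 1 mol m^-3 = 1 mM = 1000 uM


def thermal_voltage(T: float = DEFAULT_TEMPERATURE) -> float:
    """RT/F in volts (~25.26 mV at 293 K)."""
    return GAS_CONSTANT * T / FARADAY


def mv_to_v(v_mV: float) -> float:
    return v_mV / MV_PER_V


def v_to_mv(v_V: float) -> float:
    return v_V * MV_PER_V


def um_to_mol_m3(c_uM: float) -> float:
    """Micromolar to mol m^-3 (= millimolar)."""
    return c_uM / UM_PER_MOL_M3
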