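"""Physical constants and unit conversions.

Internally the package works in SI (J, mol, K, V); public interfaces accept
and emit the conventional electrophysiology units (mV, °C, pA, nS, pS).
"""

R = 8.314
"""Gas constant, J/(mol·K)."""

F = 96485.0
"""Faraday's constant, C/mol. Gating charge in e0 is interpreted per mole,
so a charge of z e0 contributes z·F·V to the molar free energy."""

KELVIN_OFFSET = 273.15

JOULES_PER_KCAL = 4184.0


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + KELVIN_OFFSET


def mv_to_v(v_mv: float) -> float:
    return v_mv * 1e-3


def thermal_voltage_mv(temp_c: float) -> float:
    """R·T/F in mV (≈25.6 mV at 24 °C); the slope scale of Boltzmann curves."""
    return celsius_to_kelvin(temp_c) * R / F * 1e3
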