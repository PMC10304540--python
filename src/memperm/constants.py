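"""Physical constants shared across the package.

All energies are in kJ/mol, lengths in nm, times in ps. The gas constant is
therefore carried in kJ mol⁻¹ K⁻¹ so that RT at 298.15 K is ≈ 2.479 kJ/mol.
"""

from __future__ import annotations

#: Molar gas constant, kJ mol⁻¹ K⁻¹ (CODATA 2018).
R_GAS = 8.314462618e-3

#: Default absolute temperature, K.
T_DEFAULT = 298.15


def rt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy RT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_GAS * temperature


#: Unit conversion: 1 nm²/ps = 1e-14 m²/ps = 1e-2 cm²/s.
NM2_PER_PS_TO_CM2_PER_S = 1e-2

#: Unit conversion: 1 nm/ps = 1e3 m/s = 1e5 cm/s.
NM_PER_PS_TO_CM_PER_S = 1e5
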