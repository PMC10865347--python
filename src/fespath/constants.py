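"""Physical constants in package units (Å, kcal mol⁻¹, ps, K)."""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB = 0.0019872041

#: Avogadro constant, mol⁻¹.
NA = 6.02214076e23

#: Planck constant per molecule, kcal s (h expressed in kcal rather than J).
H_MOLECULAR = 1.5836687e-37

#: Boltzmann constant per molecule, kcal K⁻¹.
KB_MOLECULAR = KB / NA


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from °C to K."""
    return t_celsius + 273.15
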