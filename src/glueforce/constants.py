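"""Physical constants. Energies are kcal/mol, lengths Å, times ns throughout."""

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL_MOL_K = 0.0019872

#: Reference temperature (K) at which diffusion coefficients are specified
REFERENCE_TEMPERATURE = 298.0


def rt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol (0.59219 kcal/mol at 298 K)."""
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0 K, got {temperature}")
    return KB_KCAL_MOL_K * temperature
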