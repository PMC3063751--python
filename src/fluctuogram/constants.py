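"""Physical constants and shared defaults.

All energies are in kcal/mol, lengths in Angstrom, masses in amu and
temperatures in Kelvin, so force constants carry kcal/mol/A^2.
"""

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL = 0.0019872041

#: Default simulation/analysis temperature in Kelvin.
DEFAULT_TEMPERATURE = 300.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Return k_B*T in kcal/mol (0.59616 kcal/mol at 300 K)."""
    return BOLTZMANN_KCAL * temperature
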