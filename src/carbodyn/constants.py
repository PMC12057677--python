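"""Unit conventions used throughout the package.

Lengths are in Angstrom, times in picoseconds, energies in kcal/mol and
temperatures in Kelvin.  All free-energy estimators take kT in kcal/mol.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872041

#: Default simulation temperature (K); elevated to mimic nuclear quantum
#: effects on the liquid structure.
DEFAULT_TEMPERATURE_K = 330.0

#: Atomic masses (g/mol) for the species this package handles.
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "O": 15.999}

#: Avogadro constant (1/mol).
N_AVOGADRO = 6.02214076e23


def kT(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in kcal/mol at the given temperature."""
    return KB_KCAL_PER_MOL_K * temperature_k
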