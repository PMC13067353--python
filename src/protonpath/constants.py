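"""Physical constants (CODATA 2018) and unit-conversion factors.

All energies in this package are kcal/mol, lengths in Angstrom, temperatures
in Kelvin.  Everything that converts between units goes through this table so
rates and conversions are bit-reproducible.
"""

# SI defining constants
BOLTZMANN_J_PER_K = 1.380649e-23       # k_B, J/K (exact)
PLANCK_J_S = 6.62607015e-34            # h, J*s (exact)
AVOGADRO_PER_MOL = 6.02214076e23       # N_A, 1/mol (exact)
ELEMENTARY_CHARGE_C = 1.602176634e-19  # e, C (exact)

# thermochemical calorie
JOULE_PER_CAL = 4.184

# gas constant, kcal/(mol*K)
R_KCAL_PER_MOL_K = BOLTZMANN_J_PER_K * AVOGADRO_PER_MOL / (JOULE_PER_CAL * 1000.0)
# = 1.987204e-3 kcal/(mol K)

# 1 eV per particle expressed per mole, kcal/mol
EV_TO_KCAL_PER_MOL = ELEMENTARY_CHARGE_C * AVOGADRO_PER_MOL / (JOULE_PER_CAL * 1000.0)
# = 23.060548 kcal/mol

KJ_TO_KCAL = 1.0 / JOULE_PER_CAL

DEFAULT_TEMPERATURE_K = 310.0


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL_PER_MOL_K * temperature


def eyring_prefactor(temperature: float) -> float:
    """Attempt frequency k_B*T/h in 1/s."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_J_PER_K * temperature / PLANCK_J_S
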