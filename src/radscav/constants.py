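"""Physical constants and unit conversions.

All energies cross module boundaries in kcal mol^-1 (the working unit of
thermochemical tables); SI units are used internally for the diffusion
arithmetic.  Every conversion in the package goes through this module.
"""

from __future__ import annotations

import math

# CODATA 2018 exact values
BOLTZMANN_J_PER_K = 1.380649e-23  # k_B, J K^-1
PLANCK_J_S = 6.62607015e-34  # h, J s
AVOGADRO_PER_MOL = 6.02214076e23  # N_A, mol^-1
SPEED_OF_LIGHT_CM_S = 2.99792458e10  # c, cm s^-1

# Gas constant in thermochemical units
GAS_CONSTANT_KCAL = 1.987204e-3  # R, kcal mol^-1 K^-1
# Gas constant in L atm mol^-1 K^-1 (for standard-state conversions)
GAS_CONSTANT_L_ATM = 0.0820574

KCAL_PER_MOL_TO_J = 4184.0 / AVOGADRO_PER_MOL  # one kcal/mol, in J per molecule

# hc/k_B in cm K: converts a wavenumber to a temperature
WAVENUMBER_TO_KELVIN = PLANCK_J_S * SPEED_OF_LIGHT_CM_S / BOLTZMANN_J_PER_K


def kbt_over_h(temperature: float) -> float:
    """Universal TST frequency factor k_B*T/h in s^-1 (6.2124e12 at 298.15 K)."""
    return BOLTZMANN_J_PER_K * temperature / PLANCK_J_S


def boltzmann_factor(energy_kcal: float, temperature: float) -> float:
    """exp(-E/RT) for an energy in kcal mol^-1."""
    return math.exp(-energy_kcal / (GAS_CONSTANT_KCAL * temperature))


def kcal_to_joule_per_molecule(energy_kcal: float) -> float:
    return energy_kcal * KCAL_PER_MOL_TO_J


def wavenumber_to_joule(nu_cm: float) -> float:
    """Photon/vibrational quantum h*c*nu for a wavenumber in cm^-1, in J."""
    return PLANCK_J_S * SPEED_OF_LIGHT_CM_S * nu_cm


def atm_to_molar_standard_state(delta_g_kcal: float, temperature: float,
                                delta_n: int = -1) -> float:
    """Re-reference a free energy from the 1 atm to the 1 M standard state.

    For a bimolecular activation step A + B -> TS the mole change is
    delta_n = -1 and the barrier drops by RT*ln(R'T) (~1.89 kcal/mol at
    298.15 K).  Channel tables shipped with this package are already on the
    1 M scale; this helper is for users bringing raw gas-phase output.
    """
    molar_volume = GAS_CONSTANT_L_ATM * temperature  # L/mol of ideal gas at 1 atm
    return delta_g_kcal + delta_n * GAS_CONSTANT_KCAL * temperature * math.log(molar_volume)
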