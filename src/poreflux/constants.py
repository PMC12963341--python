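"""Physical constants and the package-wide unit conventions.

All quantities in this package use a single fixed unit system:

======================  ========
length                  nm
time                    ns
voltage                 mV
current                 pA
conductance             nS
energy                  kT (thermal units at the configured temperature)
diffusion coefficient   nm^2/ns
concentration           mol/L
======================  ========

Every conversion between these units and SI lives here; no other module
hard-codes a physical constant.
"""

from __future__ import annotations

#: Elementary charge (C).
ELEMENTARY_CHARGE_C = 1.602e-19

#: Boltzmann constant (J/K).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Avogadro constant (1/mol).
AVOGADRO_PER_MOL = 6.02214076e23


def kT_joule(temperature_K: float) -> float:
    """Thermal energy kT in joules at the given temperature."""
    return BOLTZMANN_J_PER_K * temperature_K


def molar_to_per_nm3(conc_mol_per_L: float) -> float:
    """Convert a molar concentration to a number density in 1/nm^3.

    1 mol/L = N_A / (1e24 nm^3) ions per nm^3 ≈ 0.602 nm^-3.
    """
    return conc_mol_per_L * AVOGADRO_PER_MOL * 1e-24


def charges_per_ns_to_pA(rate_per_ns: float) -> float:
    """Convert an elementary-charge transfer rate (1/ns) to a current in pA.

    One elementary charge per ns is 1.602e-19 C / 1e-9 s = 160.2 pA.
    """
    return rate_per_ns * ELEMENTARY_CHARGE_C * 1e21
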