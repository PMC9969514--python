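"""Reduced-unit conventions and the physical length scale of the model.

The model works in standard DPD reduced units: bead mass = 1, thermal energy
k_B*T = 1 and the water-water interaction cutoff r_c = 1 as the unit of
length.  The physical size of r_c follows from the coarse-graining choices:
each water bead represents N_m = 2 water molecules, and pure water is
represented at a reduced bead number density rho*r_c^3 = 3.  One mole of DPD
"volume elements" then occupies

    N_A * r_c^3 = rho*r_c^3 * N_m * V_w

with V_w ~ 18 mL/mol the molar volume of water, giving r_c ~ 5.64 Angstrom.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol
WATER_MOLAR_VOLUME_M3 = 18.0e-6  # m^3/mol at 25 C
MAPPING_NUMBER = 2  # water molecules per water bead
WATER_BEAD_DENSITY = 3.0  # rho * r_c^3 for pure water

#: DPD time unit tau expressed in integration steps at the standard dt=0.01
STEPS_PER_TAU = 100


def dpd_element_molar_volume(
    rho_rc3: float = WATER_BEAD_DENSITY,
    mapping_number: int = MAPPING_NUMBER,
    water_molar_volume: float = WATER_MOLAR_VOLUME_M3,
) -> float:
    """Molar volume N_A*r_c^3 of DPD volume elements, in m^3/mol."""
    return rho_rc3 * mapping_number * water_molar_volume


def rc_in_angstrom(
    rho_rc3: float = WATER_BEAD_DENSITY,
    mapping_number: int = MAPPING_NUMBER,
    water_molar_volume: float = WATER_MOLAR_VOLUME_M3,
) -> float:
    """Physical size of the DPD length unit r_c in Angstrom."""
    rc3_m3 = dpd_element_molar_volume(rho_rc3, mapping_number, water_molar_volume) / AVOGADRO
    return (rc3_m3 ** (1.0 / 3.0)) * 1e10
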