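"""Physical constants, unit scales, and helical-repeat arithmetic.

All energies are in kcal/mol, lengths in Å, angles in degrees unless
noted. The nondimensionalization scales (1 Å for translations, 11° for
rotations) make the mixed-unit stiffness matrix dimensionally uniform so
its spectrum is meaningful: the angle scale is numerically close to the
twist density of both the B-DNA helix (360°/34 Å pitch = 10.6°/Å) and
the A-RNA helix (360°/32 Å = 11.3°/Å), and a single common value of 11°
is used for both duplex types.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kcal/mol/K.
KB = 1.987204e-3

#: Reference temperature (K) of the underlying ensembles.
T = 300.0

#: Thermal energy kB*T at 300 K, kcal/mol.
KBT = KB * T  # 0.5961612 kcal/mol

#: 1 kcal/(mol*Å) expressed in piconewtons.
KCAL_PER_MOL_ANGSTROM_IN_PN = 69.479

#: Thermal energy in pN*Å (used for the stretch modulus).
KBT_PN_ANGSTROM = KBT * KCAL_PER_MOL_ANGSTROM_IN_PN

#: Nondimensionalization scale for translational coordinates (Å).
LENGTH_SCALE = 1.0

#: Nondimensionalization scale for rotational coordinates (deg).
ANGLE_SCALE = 11.0

#: Default eigenvalue cutoffs for repairing assembled stiffness matrices,
#: applied on the nondimensionalized (kcal/mol) scale.
LAMBDA_C = {"DNA": 0.48, "RNA": 0.44}


def angle_scale_from_helix(bp_per_turn: float, rise_per_bp: float) -> float:
    """Twist density (deg/Å) of a helix with the given repeat and rise.

    The helical pitch is ``bp_per_turn * rise_per_bp`` and the twist
    density 360/pitch; e.g. B-DNA with 10.5 bp/turn and 3.23 Å rise has
    a pitch of ~34 Å and a twist density of ~10.6 deg/Å.
    """
    if bp_per_turn <= 0 or rise_per_bp <= 0:
        raise ValueError("bp_per_turn and rise_per_bp must be positive")
    return 360.0 / (bp_per_turn * rise_per_bp)


def helical_repeat(twist_deg: float) -> float:
    """Helical repeat (bp/turn) implied by a mean twist per step in degrees."""
    if twist_deg <= 0:
        raise ValueError("twist must be positive")
    return 360.0 / twist_deg


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the model's physical constants and unit scales."""

    kB: float = KB
    T: float = T
    kBT: float = KBT
    length_scale: float = LENGTH_SCALE
    angle_scale: float = ANGLE_SCALE
    lambda_c_dna: float = LAMBDA_C["DNA"]
    lambda_c_rna: float = LAMBDA_C["RNA"]
    force_conversion_pn: float = KCAL_PER_MOL_ANGSTROM_IN_PN

    def lambda_c(self, na_type: str) -> float:
        return LAMBDA_C[na_type.upper()]


CONSTANTS = PhysicalConstants()
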