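"""Conversions between DPD reduced units and physical units.

The coarse-grained water bead stands for ``N_m`` water molecules.  Together
with the reduced bead density ``rho rc^3`` this fixes the physical size of the
DPD length unit ``rc`` through the identity

    N_A rc^3 = (rho rc^3) * N_m * V_m

where ``V_m`` is the molar volume of water.  With the defaults (``N_m = 2``,
``V_m = 18e-6 m^3/mol``, ``rho rc^3 = 3``) one mole of rc-cubes occupies about
0.108 L and ``rc = 5.64 Å``.  The same volume converts bead counts in a box of
side ``L`` (in rc) to molar concentrations, which is how both salt loadings
and CMC estimates are expressed in mol/L.

All public functions are pure; nothing here depends on the simulation engine.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import constants

__all__ = [
    "MappingContext",
    "DEFAULT_MAPPING",
    "MOLAR_DPD_VOLUME_L",
    "rc_from_mapping",
    "coupling_gamma",
    "salt_pairs_for_concentration",
    "concentration_from_salt_pairs",
    "molar_concentration",
]

#: Molar volume of one mole of rc^3 cells at the default mapping, litres/mol,
#: at the 3-significant-figure working precision used throughout the
#: parameterization (the unrounded value is MappingContext.molar_dpd_volume_L).
MOLAR_DPD_VOLUME_L = 0.108


@dataclass(frozen=True)
class MappingContext:
    """Physical interpretation of the DPD unit system.

    Parameters
    ----------
    mapping_number:
        Water molecules represented by one water bead (``N_m``).
    molar_volume:
        Molar volume of water in m^3/mol.
    reduced_density:
        Bead number density in units of rc^-3 (``rho rc^3``).
    """

    mapping_number: float = 2.0
    molar_volume: float = 18.0e-6
    reduced_density: float = 3.0

    def __post_init__(self) -> None:
        if min(self.mapping_number, self.molar_volume, self.reduced_density) <= 0:
            raise ValueError("mapping parameters must be positive")

    @property
    def rc_m(self) -> float:
        """DPD length unit rc in metres."""
        v = self.reduced_density * self.mapping_number * self.molar_volume
        return (v / constants.N_A) ** (1.0 / 3.0)

    @property
    def rc_angstrom(self) -> float:
        return self.rc_m * 1e10

    @property
    def molar_dpd_volume_L(self) -> float:
        """Exact N_A rc^3 in litres per mole (unrounded)."""
        return constants.N_A * self.rc_m**3 * 1e3


DEFAULT_MAPPING = MappingContext()


def rc_from_mapping(
    mapping_number: float = 2.0,
    molar_volume: float = 18.0e-6,
    reduced_density: float = 3.0,
) -> float:
    """Physical rc in angstroms implied by the water-bead mapping."""
    ctx = MappingContext(mapping_number, molar_volume, reduced_density)
    return ctx.rc_angstrom


def coupling_gamma(
    temperature: float = 298.0,
    relative_permittivity: float = 78.3,
    rc: float | None = None,
) -> float:
    """Dimensionless electrostatic coupling Gamma = e^2/(kB T eps0 eps_r rc).

    ``rc`` is in metres; the default is the rc of :data:`DEFAULT_MAPPING`.
    Gamma is 4*pi times the Bjerrum length expressed in rc units and sets the
    strength of all charge-charge interactions in reduced units.
    """
    if rc is None:
        rc = DEFAULT_MAPPING.rc_m
    if temperature <= 0 or relative_permittivity <= 0 or rc <= 0:
        raise ValueError("temperature, permittivity and rc must be positive")
    e = constants.e
    return e**2 / (
        constants.k * temperature * constants.epsilon_0 * relative_permittivity * rc
    )


def salt_pairs_for_concentration(
    c_salt: float,
    box_side: float,
    ctx: MappingContext = DEFAULT_MAPPING,
    molar_dpd_volume: float = MOLAR_DPD_VOLUME_L,
    count_ions: bool = False,
) -> int:
    """Number of cation/anion bead pairs realizing a salt molarity.

    One "salt" is one cation bead plus one anion bead, inserted by replacing
    two water beads, so the box stays electroneutral and at constant density.
    ``box_side`` is in rc.  With ``count_ions=True`` the count of individual
    ion beads (twice the pair count) is returned instead.
    """
    if c_salt < 0:
        raise ValueError("salt concentration must be non-negative")
    if box_side <= 0:
        raise ValueError("box side must be positive")
    pairs = int(round(c_salt * box_side**3 * molar_dpd_volume))
    return 2 * pairs if count_ions else pairs


def concentration_from_salt_pairs(
    n_pairs: int,
    box_side: float,
    ctx: MappingContext = DEFAULT_MAPPING,
    molar_dpd_volume: float = MOLAR_DPD_VOLUME_L,
) -> float:
    """Inverse of :func:`salt_pairs_for_concentration`, in mol/L."""
    if n_pairs < 0:
        raise ValueError("pair count must be non-negative")
    if box_side <= 0:
        raise ValueError("box side must be positive")
    return n_pairs / (box_side**3 * molar_dpd_volume)


def molar_concentration(
    n_molecules: float,
    box_side: float,
    molar_dpd_volume: float = MOLAR_DPD_VOLUME_L,
) -> float:
    """Molar concentration of ``n_molecules`` objects in an ``L^3`` rc-box."""
    if box_side <= 0:
        raise ValueError("box side must be positive")
    return n_molecules / (box_side**3 * molar_dpd_volume)
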