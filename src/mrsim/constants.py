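"""Physical constants and material properties of the condensing polymer.

The condensate is low-molecular-weight polyethylene glycol (PEG), an
oligomer HO-(C2H4O)_M-H. The nominal material is PEG 300 (M = 6,
molecular weight ~300 Da), which is liquid at room temperature and has a
vapor pressure low enough to be stable for hours once deposited but high
enough to evaporate from a ~100 C reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "PEGProperties",
    "CODATA",
    "molecule_mass",
    "molecule_volume",
]

#: mass of one ethylene-oxide monomer unit (C2H4O) in daltons
MONOMER_MASS_DA = 44.053
#: mass of the H / OH end groups (one water equivalent) in daltons
END_GROUP_MASS_DA = 18.015


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed CODATA constants (not configurable)."""

    boltzmann_k: float = 1.380649e-23  # J/K
    gravity_g: float = 9.80665  # m/s^2
    atomic_mass_unit: float = 1.66053906892e-27  # kg

    def __post_init__(self) -> None:
        if min(self.boltzmann_k, self.gravity_g, self.atomic_mass_unit) <= 0:
            raise ValueError("physical constants must be strictly positive")


CODATA = PhysicalConstants()


def molecule_mass(n_monomers: int, constants: PhysicalConstants = CODATA) -> float:
    """Mass in kg of one HO-(C2H4O)_M-H molecule.

    Parameters
    ----------
    n_monomers
        Number of ethylene-oxide monomer units M (non-negative integer).
        M = 0 degenerates to a water molecule (the bare end groups).
    """
    m = int(n_monomers)
    if m != n_monomers or m < 0:
        raise ValueError(f"n_monomers must be a non-negative integer, got {n_monomers!r}")
    da = m * MONOMER_MASS_DA + END_GROUP_MASS_DA
    return da * constants.atomic_mass_unit


def molecule_volume(molecule_mass_kg: float, liquid_density: float) -> float:
    """Volume in m^3 occupied by one molecule in the liquid phase, m1 / rho."""
    if liquid_density <= 0:
        raise ValueError(f"liquid density must be positive, got {liquid_density}")
    if molecule_mass_kg < 0:
        raise ValueError(f"molecule mass must be non-negative, got {molecule_mass_kg}")
    return molecule_mass_kg / liquid_density


@dataclass(frozen=True)
class PEGProperties:
    """Material constants of the condensing PEG oligomer.

    Defaults describe PEG 300: M = 6 monomers, liquid density
    1130 kg/m^3, surface tension 43.5 mN/m, refractive index 1.46.
    ``molecule_mass_kg`` / ``molecule_volume_m3`` are derived from the
    composition and density when not given explicitly.
    """

    n_monomers: int = 6
    liquid_density: float = 1130.0  # kg/m^3
    surface_tension: float = 0.0435  # N/m
    refractive_index: float = 1.46
    molecule_mass_kg: float = field(default=0.0)
    molecule_volume_m3: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")
        if self.surface_tension <= 0:
            raise ValueError("surface tension must be positive")
        if not (1.3 < self.refractive_index < 1.6):
            raise ValueError("refractive index outside the physical liquid range (1.3, 1.6)")
        if self.molecule_mass_kg == 0.0:
            object.__setattr__(self, "molecule_mass_kg", molecule_mass(self.n_monomers))
        if self.molecule_volume_m3 == 0.0:
            object.__setattr__(
                self,
                "molecule_volume_m3",
                molecule_volume(self.molecule_mass_kg, self.liquid_density),
            )
        # density / molecular mass / molecular volume must be consistent
        implied = self.molecule_volume_m3 * self.liquid_density
        if abs(implied - self.molecule_mass_kg) > 0.02 * self.molecule_mass_kg:
            raise ValueError(
                "inconsistent PEG properties: molecule_mass deviates from "
                "liquid_density * molecule_volume by more than 2%"
            )
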