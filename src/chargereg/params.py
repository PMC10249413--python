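"""Model parameters: the titratable surface and the salt reservoir.

The surface is a planar wall carrying acidic sites (-OH <-> -O- + H+)
on a square lattice; the bath is a bulk electrolyte in the primitive
model.  All lengths are in nm, areal densities in nm^-2, bulk densities
in nm^-3.  SI quantities (capacitances in F/m^2, charge densities in
mC/m^2) are produced only by the reporting helpers below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    molar_to_number_density,
)

__all__ = [
    "SurfaceModel",
    "IonSpecies",
    "SaltBath",
    "permittivity_from_bjerrum",
    "stern_capacitance",
    "excluded_volume_capacitance",
    "effective_capacitance",
    "max_surface_charge",
    "sigma_to_mC_per_m2",
]


@dataclass(frozen=True)
class SurfaceModel:
    """Fixed physical parameters of the titratable wall.

    Attributes
    ----------
    bjerrum_length
        Bjerrum length l_B in nm (0.714 nm for water at room temperature).
    site_density
        Areal density of titratable sites, sigma^site, in nm^-2.
    pKa
        Intrinsic acid dissociation constant of a surface group.
    d_is
        Closest perpendicular separation between an ion charge and a
        site charge (the Stern-layer thickness), nm.
    d_ii
        Closest separation between two ion charges, nm.
    zeta
        Site-site correlation attenuation, 0 <= zeta <= 1.  zeta = 0
        switches site-site correlations off; zeta = 1 is the perfect
        lattice-gas limit.
    xi2
        Ion-site correlation factor xi^2 >= 1 entering the contact-value
        boundary condition; 1 means ion-site correlations are neglected.
    temperature
        Absolute temperature in K, used only for SI conversions.
    """

    bjerrum_length: float = 0.714
    site_density: float = 4.8
    pKa: float = 7.7
    d_is: float = 0.35
    d_ii: float = 0.4
    zeta: float = 0.75
    xi2: float = 1.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.bjerrum_length <= 0:
            raise ValueError("bjerrum_length must be > 0")
        if self.site_density <= 0:
            raise ValueError("site_density must be > 0")
        if self.d_is <= 0 or self.d_ii < 0:
            raise ValueError("contact distances must be positive (d_ii may be 0)")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")
        if self.xi2 < 1.0:
            raise ValueError("xi2 must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species of the bulk reservoir."""

    valency: int
    concentration: float  # mol/L

    def __post_init__(self) -> None:
        if self.valency == 0:
            raise ValueError("ionic valency must be nonzero")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def density(self) -> float:
        """Bulk number density in nm^-3."""
        return molar_to_number_density(self.concentration)


@dataclass(frozen=True)
class SaltBath:
    """Bulk electrolyte: a list of ionic species, electroneutral overall."""

    species: tuple[IonSpecies, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        species = tuple(
            s if isinstance(s, IonSpecies) else IonSpecies(*s) for s in self.species
        )
        object.__setattr__(self, "species", species)
        net = sum(s.valency * s.density for s in species)
        scale = sum(abs(s.valency) * s.density for s in species)
        if scale > 0:
            if abs(net) > 1e-12 * scale:
                raise ValueError(
                    f"bath is not electroneutral: sum z_i rho_i = {net:g} nm^-3"
                )
            has_cat = any(s.valency > 0 and s.concentration > 0 for s in species)
            has_an = any(s.valency < 0 and s.concentration > 0 for s in species)
            if not (has_cat and has_an):
                raise ValueError("a nonempty bath needs at least one cation and one anion")

    @classmethod
    def z_one(cls, z: int, conc_molar: float) -> "SaltBath":
        """A z:1 salt: cations of valency z at ``conc_molar``, monovalent
        anions at z times that concentration (e.g. ``z_one(2, 1.0)`` is
        1 M CaCl2)."""
        if z < 1:
            raise ValueError("cation valency must be >= 1")
        return cls(species=(IonSpecies(z, conc_molar), IonSpecies(-1, z * conc_molar)))

    @property
    def valencies(self) -> tuple[int, ...]:
        return tuple(s.valency for s in self.species)

    @property
    def densities(self) -> tuple[float, ...]:
        """Bulk number densities rho_i^bulk in nm^-3."""
        return tuple(s.density for s in self.species)

    @property
    def total_density(self) -> float:
        """Total bulk ion density in nm^-3."""
        return sum(self.densities)

    def is_symmetric_1_1(self) -> bool:
        """True for a single symmetric monovalent salt."""
        active = [s for s in self.species if s.concentration > 0]
        if len(active) != 2:
            return False
        (a, b) = active
        return {a.valency, b.valency} == {1, -1} and math.isclose(
            a.concentration, b.concentration, rel_tol=1e-12
        )


# ---------------------------------------------------------------------------
# SI reporting helpers


def permittivity_from_bjerrum(model: SurfaceModel) -> float:
    """Absolute permittivity eps0*eps_r (F/m) implied by the Bjerrum length.

    Inverts l_B = e^2 / (4 pi eps0 eps_r k_B T) at the model temperature.
    """
    l_b_m = model.bjerrum_length * 1e-9
    return ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * l_b_m * BOLTZMANN * model.temperature
    )


def stern_capacitance(model: SurfaceModel) -> float:
    """Stern-layer capacitance C_S = eps0*eps_r / d_is, in F/m^2.

    The charge-free gap of thickness d_is between the site plane and the
    plane of closest ion approach acts as a parallel-plate capacitor.
    """
    return permittivity_from_bjerrum(model) / (model.d_is * 1e-9)


def excluded_volume_capacitance(model: SurfaceModel) -> float:
    """The (negative) excluded-volume capacitance C_ex = -eps0*eps_r/(d_ii/4), F/m^2.

    The finite ion size deepens the potential an ion feels at contact by
    a term linear in sigma, formally a capacitor of plate distance
    d_ii/4 wired with opposite sign to the Stern capacitor.
    """
    if model.d_ii == 0:
        return -math.inf
    return -permittivity_from_bjerrum(model) / (model.d_ii / 4.0 * 1e-9)


def effective_capacitance(model: SurfaceModel) -> float:
    """Series combination C_eff = (C_S^-1 + C_ex^-1)^-1 in F/m^2.

    Equals eps0*eps_r / (d_is - d_ii/4); the excluded-volume capacitor is
    negative-valued, so C_eff >= C_S.  This is the capacitance a
    mean-field fit without excluded volume would effectively need.
    """
    gap = model.d_is - model.d_ii / 4.0
    if gap <= 0:
        raise ValueError(
            f"nonphysical effective capacitor: d_is = {model.d_is} nm must "
            f"exceed d_ii/4 = {model.d_ii / 4.0} nm"
        )
    return permittivity_from_bjerrum(model) / (gap * 1e-9)


def max_surface_charge(model: SurfaceModel) -> float:
    """Surface charge density at full ionization, -e*sigma^site, in mC/m^2."""
    return -ELEMENTARY_CHARGE * model.site_density * 1e18 * 1e3


def sigma_to_mC_per_m2(sigma_nm2: float) -> float:
    """Convert a signed areal charge number density (nm^-2, in units of e)
    to mC/m^2."""
    return ELEMENTARY_CHARGE * sigma_nm2 * 1e18 * 1e3
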