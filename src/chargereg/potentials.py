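"""Correction potentials at the interface, as dimensionless x = beta*e*phi.

The total potential on an ion at contact decomposes as
x_ion = x_mf + x_ii + x_ex (mean field, ion-ion correlations, excluded
volume), and the potential on a surface site as
x_site = x_mf + x_cap + x_ss (mean field, Stern capacitor, site-site
correlations).  The mean-field piece is common to both and drops out of
the self-consistent loop; this module provides the four correction
terms together with the interface descriptors z_s (average contact
valency) and Xi (average electrostatic coupling parameter).

Sign conventions, for an acid surface (sigma <= 0): x_cap <= 0 and
x_ex <= 0 (both deepen the attraction of counterions / the site
potential), x_ss >= 0 (ordered sites lower their mutual repulsion,
reducing |x_site|), x_ii <= 0 (correlated counterions gain energy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .madelung import M_HEX, M_SQUARE
from .params import SaltBath, SurfaceModel

__all__ = [
    "C0",
    "PotentialBreakdown",
    "x_capacitance",
    "x_excluded_volume",
    "x_site_site",
    "contact_valency",
    "coupling_parameter",
    "x_ion_ion",
]

#: One-loop ion-ion correlation coefficient, pi/8 - 0.3104.
C0: float = math.pi / 8.0 - 0.3104

_ZS_FLOOR = 1e-12  # below this, x_ii is identically 0 (analytic limit)


@dataclass(frozen=True)
class PotentialBreakdown:
    """All correction potentials and interface descriptors at one state.

    x_cap, x_ex, x_ss, x_ii are the dimensionless correction potentials;
    z_s is the average valency of ions at contact (>= 0) and Xi the
    average coupling parameter 2*pi*l_B^2*|sigma|*z_s^3.
    """

    x_cap: float = 0.0
    x_ex: float = 0.0
    x_ss: float = 0.0
    x_ii: float = 0.0
    z_s: float = 0.0
    Xi: float = 0.0


def x_capacitance(sigma: float, model: SurfaceModel) -> float:
    """Stern-capacitor potential x_cap = 4*pi*l_B*d_is*sigma.

    Dimensionless form of e*sigma/C_S with C_S = eps0*eps_r/d_is; linear
    in the (signed) surface charge density sigma (nm^-2).
    """
    return 4.0 * math.pi * model.bjerrum_length * model.d_is * sigma


def x_excluded_volume(sigma: float, model: SurfaceModel) -> float:
    """Excluded-volume potential x_ex = pi*l_B*d_ii*sigma.

    A capacitor-like hole correction with effective plate distance
    d_ii/4: the finite ion diameter keeps other ion charges out of a
    contact zone, increasing the contact potential in absolute terms.
    """
    return math.pi * model.bjerrum_length * model.d_ii * sigma


def x_site_site(alpha: float, model: SurfaceModel) -> float:
    """Site-site correlation potential x_ss = +zeta*M_sq*l_B*sqrt(alpha*sigma_site).

    The ionized sites arrange to maximize their mutual distances on the
    square site lattice; the corresponding 2D Wigner-crystal Madelung
    energy (per charge, at the ionized-site density alpha*sigma_site)
    lowers the energy of the charged state, i.e. raises x_site.  zeta in
    [0, 1] attenuates the perfect-lattice value for the entropy of the
    partially occupied lattice gas; zeta = 0 disables the term.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"ionized fraction alpha must lie in [0, 1], got {alpha}")
    return (
        model.zeta
        * M_SQUARE
        * model.bjerrum_length
        * math.sqrt(alpha * model.site_density)
    )


def contact_valency(x_ion: float, bath: SaltBath) -> float:
    """Average valency z_s of the ions residing at the interface.

    z_s = |sum_i z_i rho_i^s| / sum_i rho_i^s with the contact densities
    rho_i^s = rho_i^bulk * exp(-z_i * x_ion).  Zero at zero surface
    charge (x_ion = 0, by bulk electroneutrality); tends to the
    counterion valency for strongly charged surfaces.
    """
    if bath.total_density == 0:
        warnings.warn("contact_valency of an empty bath is undefined; returning 0")
        return 0.0
    num = 0.0
    den = 0.0
    for z, rho in zip(bath.valencies, bath.densities):
        w = rho * math.exp(min(-z * x_ion, 700.0))
        num += z * w
        den += w
    return abs(num) / den


def coupling_parameter(sigma: float, z_s: float, model: SurfaceModel) -> float:
    """Average electrostatic coupling parameter Xi = 2*pi*l_B^2*|sigma|*z_s^3."""
    if z_s < 0:
        raise ValueError("z_s must be >= 0")
    return 2.0 * math.pi * model.bjerrum_length**2 * abs(sigma) * z_s**3


def x_ion_ion(Xi: float, z_s: float, model: SurfaceModel) -> float:
    """Ion-ion correlation potential x_ii, interpolating loop and Madelung limits.

    At weak coupling the one-loop correction gives x_ii = -c0*Xi/z_s
    with c0 = pi/8 - 0.3104; at strong coupling the energy is capped by
    the Madelung energy of a hexagonal crystal of bound counterions
    (areal density |sigma|/z_s), which expressed through Xi reads
    x_ii = -M_hex*sqrt(Xi)/(sqrt(2*pi)*z_s).  The two regimes are joined
    by the quadratic inverse-sum interpolation

        x_ii = -(1/z_s) * [ (c0*Xi)^-2 + (M_hex*sqrt(Xi/(2*pi)))^-2 ]^(-1/2),

    a smooth function whose magnitude is a strict lower bound of either
    asymptote and which approaches each limit quadratically in the
    asymptote ratio, so the loop correction is barely attenuated until
    the Madelung cap actually comes into reach (the crossover sits at
    Xi = (M_hex/c0)^2/(2*pi), about 90).
    """
    if Xi < 0:
        raise ValueError("Xi must be >= 0")
    if Xi == 0.0 or z_s < _ZS_FLOOR:
        return 0.0
    loop = C0 * Xi
    madelung = M_HEX * math.sqrt(Xi / (2.0 * math.pi))
    return -(1.0 / z_s) * (loop**-2 + madelung**-2) ** -0.5
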