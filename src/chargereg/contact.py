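"""Contact-value boundary condition for the ion potential at the wall.

For a planar charged wall in contact with a bulk electrolyte the
contact-value theorem fixes the excess ion density at the surface:

    sum_i rho_i^bulk * (exp(-z_i * x_ion) - 1) = 2*pi*l_B*xi2*sigma^2 + betaP

where x_ion is the dimensionless electrostatic potential on an ion at
contact, xi2 >= 1 absorbs ion-site correlation enhancement of the
contact force, and betaP is an externally imposed osmotic pressure
(nonzero for two interacting surfaces at finite separation).

For an electroneutral bath the left side is convex with minimum 0 at
x_ion = 0, so a positive right side has exactly two roots; the solver
returns the counterion-enriched branch, sign(x_ion) = sign(sigma).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .params import SaltBath, SurfaceModel
from .constants import molar_to_number_density

__all__ = ["ContactCondition", "NoSolutionError", "solve_x_ion", "grahame_closed_form"]

logger = logging.getLogger(__name__)

_EXP_MAX = 700.0  # exp overflow guard


class NoSolutionError(ValueError):
    """The contact condition has no root for the given bath and pressure."""


@dataclass(frozen=True)
class ContactCondition:
    """Inputs of one contact-theorem solve.

    sigma: signed surface charge density (nm^-2, units of e);
    xi2: ion-site correlation factor multiplying 2*pi*l_B*sigma^2;
    betaP: external osmotic pressure in k_B T/nm^3 (0 for a single wall).
    """

    sigma: float
    xi2: float = 1.0
    betaP: float = 0.0

    def __post_init__(self) -> None:
        if self.xi2 < 1.0:
            raise ValueError("xi2 must be >= 1")

    def rhs(self, model: SurfaceModel) -> float:
        """Right side 2*pi*l_B*xi2*sigma^2 + betaP (nm^-3)."""
        return (
            2.0 * math.pi * model.bjerrum_length * self.xi2 * self.sigma**2
            + self.betaP
        )


def _excess_contact_density(x: float, bath: SaltBath) -> float:
    """Left side sum_i rho_i (exp(-z_i x) - 1), overflow-safe."""
    total = 0.0
    for z, rho in zip(bath.valencies, bath.densities):
        total += rho * math.expm1(min(-z * x, _EXP_MAX))
    return total


def solve_x_ion(
    cond: ContactCondition, bath: SaltBath, model: SurfaceModel
) -> float:
    """Solve the contact condition for x_ion on the counterion branch.

    Returns the root with sign(x_ion) = sign(sigma); 0 when both sigma
    and betaP vanish.  The root is bracketed by doubling and polished
    with Brent's method to machine precision.

    Raises
    ------
    NoSolutionError
        If the right side is negative (betaP more attractive than
        -2*pi*l_B*xi2*sigma^2): the excess contact density of an
        electroneutral bath is bounded below by 0, so no potential can
        produce a net contact depletion.
    """
    if bath.total_density == 0:
        raise NoSolutionError("salt bath has zero total concentration")
    rhs = cond.rhs(model)
    scale = max(rhs, bath.total_density)
    if rhs < 0:
        raise NoSolutionError(
            f"contact condition unsolvable: betaP = {cond.betaP:g} nm^-3 drives the "
            f"required contact excess to {rhs:g} < 0, below the bath's depletion "
            "capacity (the excess contact density of an electroneutral bath is >= 0)"
        )
    if rhs == 0.0:
        return 0.0

    direction = -1.0 if cond.sigma < 0 else 1.0
    if cond.sigma == 0.0:
        # pure-pressure case: pick the cation-enrichment (negative) branch
        direction = -1.0

    def f(x: float) -> float:
        return _excess_contact_density(x, bath) - rhs

    hi = 0.0  # f(0) = -rhs < 0
    lo = direction * 1.0
    n_expand = 0
    while f(lo) < 0.0:
        hi = lo
        lo *= 2.0
        n_expand += 1
        if n_expand > 60:  # |x| > 2^60: unreachable for physical input
            raise NoSolutionError("bracket expansion failed for the contact condition")
    a, b = (lo, hi) if lo < hi else (hi, lo)
    x = brentq(f, a, b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    logger.debug(
        "contact solve: sigma=%g rhs=%g bracket=(%g,%g) expansions=%d x=%g",
        cond.sigma, rhs, a, b, n_expand, x,
    )
    residual = f(x)
    assert abs(residual) < 1e-10 * scale, f"contact residual {residual:g}"
    return x


def grahame_closed_form(
    sigma: float,
    conc_1_1: float,
    model: SurfaceModel,
    xi2: float = 1.0,
) -> float:
    """Closed-form contact solution for a single symmetric 1:1 salt.

    x_ion = sign(sigma) * 2*asinh(|sigma| * sqrt(pi*l_B*xi2/(2*rho)))
    with rho the number density of either species; the analytic Grahame
    branch used as an oracle for :func:`solve_x_ion`.
    """
    if conc_1_1 <= 0:
        raise ValueError("concentration must be > 0")
    rho = molar_to_number_density(conc_1_1)
    arg = abs(sigma) * math.sqrt(math.pi * model.bjerrum_length * xi2 / (2.0 * rho))
    return math.copysign(2.0 * math.asinh(arg), sigma)
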