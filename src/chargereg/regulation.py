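"""Acid-base equilibrium of the surface sites.

The sites obey -OH + H2O <-> -O- + H3O+ with intrinsic constant pKa.
The hydronium activity is taken as its ideal part, a = 10^-pH, so every
electrostatic effect enters through the site potential x_site =
beta*e*phi^site, which shifts the equilibrium exactly like a local pH
change of x_site/ln(10).
"""

from __future__ import annotations

import math

from .constants import LN10
from .madelung import M_SQUARE
from .params import SurfaceModel

__all__ = ["ionization", "henderson_hasselbalch", "site_site_enhancement_ratio"]


def _expit(t: float) -> float:
    # overflow-safe logistic
    if t >= 0:
        return 1.0 / (1.0 + math.exp(-t))
    e = math.exp(t)
    return e / (1.0 + e)


def ionization(pH: float, x_site: float, model: SurfaceModel) -> float:
    """Ionized fraction alpha = 1 / (1 + 10^(pKa-pH) * exp(-x_site)).

    A negative site potential (attracting protons) suppresses ionization
    relative to the ideal Henderson-Hasselbalch value; the identity
    ionization(pH, x) = henderson_hasselbalch(pH + x/ln10) holds exactly.
    """
    return _expit((pH - model.pKa) * LN10 + x_site)


def henderson_hasselbalch(pH: float, model: SurfaceModel) -> float:
    """Ideal titration curve alpha_HH = 1/(1 + 10^(pKa-pH))."""
    return _expit((pH - model.pKa) * LN10)


def site_site_enhancement_ratio(alpha: float, model: SurfaceModel) -> float:
    """Predicted charge enhancement from site-site correlations alone.

    At low ionization the self-consistent effect of the site-site term
    factorizes: the charge density with the term included exceeds the
    one without by

        sigma/sigma^(a) = exp(zeta * M_sq * l_B * sqrt(alpha*sigma_site)),

    with alpha the ionized fraction of the uncorrected solution.  Used
    as a diagnostic against the full numerical ratio.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return math.exp(
        model.zeta
        * M_SQUARE
        * model.bjerrum_length
        * math.sqrt(alpha * model.site_density)
    )
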