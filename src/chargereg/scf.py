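"""Self-consistent solution of the charge-regulation problem.

At a given pH the surface charge density sigma = -alpha*sigma_site and
the interface potentials determine each other: sigma sets the Stern and
excluded-volume terms and, through the contact condition, the ion
potential x_ion, hence the contact valency z_s, the coupling parameter
Xi and the ion-ion correlation term; eliminating the common mean-field
potential gives the site potential

    x_site = (x_ion - x_ii - x_ex) + x_cap + x_ss,

from which the acid-base equilibrium returns an updated alpha.  The
fixed point is found by damped iteration (with a bisection fallback,
also exposed as an independent oracle).

Theory levels: the four corrections can be switched individually.  The
named presets follow the convention
(a) mean field with Stern + excluded-volume capacitors,
(b) = (a) + site-site correlations,
(c) = (a) + ion-ion correlations,
(d) = all terms.
The ``use_cap`` switch governs the double-layer feedback as a whole
(the mean-field potential together with its Stern correction); with
every switch off the model degenerates to the ideal
Henderson-Hasselbalch curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import potentials, regulation
from .contact import ContactCondition, solve_x_ion
from .params import SaltBath, SurfaceModel, sigma_to_mC_per_m2
from .potentials import PotentialBreakdown

__all__ = [
    "LevelSpec",
    "SolutionPoint",
    "TitrationCurve",
    "SolverOptions",
    "solve_point",
    "solve_point_bruteforce",
    "sweep",
    "relative_increase",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LevelSpec:
    """On/off switches for the four correction potentials."""

    use_cap: bool = True
    use_ex: bool = True
    use_ss: bool = True
    use_ii: bool = True

    @classmethod
    def preset(cls, letter: str) -> "LevelSpec":
        """Named theory level: 'a', 'b', 'c' or 'd' (see module docstring)."""
        try:
            return _PRESETS[letter.lower()]
        except KeyError:
            raise ValueError(
                f"unknown level preset {letter!r}; expected one of a, b, c, d"
            ) from None

    @property
    def name(self) -> str:
        for letter, spec in _PRESETS.items():
            if spec == self:
                return letter
        return "custom"


_PRESETS = {
    "a": LevelSpec(True, True, False, False),
    "b": LevelSpec(True, True, True, False),
    "c": LevelSpec(True, True, False, True),
    "d": LevelSpec(True, True, True, True),
}


@dataclass(frozen=True)
class SolverOptions:
    """Knobs of the damped fixed-point iteration."""

    tol: float = 1e-12  # on |sigma' - sigma| / sigma_site
    max_iter: int = 100_000
    damping: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass(frozen=True)
class SolutionPoint:
    """Converged state of the surface at one pH."""

    pH: float
    alpha: float
    sigma: float  # nm^-2, signed (<= 0 for the acid surface)
    sigma_SI: float  # mC/m^2
    x_ion: float
    x_site: float
    x_mf: float  # diagnostic: x_ion - x_ii - x_ex
    breakdown: PotentialBreakdown
    iterations: int
    converged: bool
    residual: float  # |sigma' - sigma| / sigma_site at exit


@dataclass(frozen=True)
class TitrationCurve:
    """Ordered solution points over a pH grid, with run metadata."""

    points: tuple[SolutionPoint, ...]
    model: SurfaceModel
    bath: SaltBath
    level: LevelSpec

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[SolutionPoint]:
        return iter(self.points)

    @property
    def pH(self) -> np.ndarray:
        return np.array([p.pH for p in self.points])

    @property
    def alpha(self) -> np.ndarray:
        return np.array([p.alpha for p in self.points])

    @property
    def all_converged(self) -> bool:
        return all(p.converged for p in self.points)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per pH with all state variables and diagnostics."""
        rows = [
            {
                "pH": p.pH,
                "alpha": p.alpha,
                "sigma_nm2": p.sigma,
                "sigma_mC_m2": p.sigma_SI,
                "x_ion": p.x_ion,
                "x_site": p.x_site,
                "x_mf": p.x_mf,
                "x_cap": p.breakdown.x_cap,
                "x_ex": p.breakdown.x_ex,
                "x_ss": p.breakdown.x_ss,
                "x_ii": p.breakdown.x_ii,
                "z_s": p.breakdown.z_s,
                "Xi": p.breakdown.Xi,
                "iterations": p.iterations,
                "converged": p.converged,
            }
            for p in self.points
        ]
        return pd.DataFrame(rows)


class _StateEvaluator:
    """One pass of the self-consistent map at fixed pH: sigma -> alpha'."""

    def __init__(
        self,
        pH: float,
        model: SurfaceModel,
        bath: SaltBath,
        level: LevelSpec,
        betaP: float = 0.0,
    ):
        self.pH = pH
        self.model = model
        self.bath = bath
        self.level = level
        self.betaP = betaP

    def evaluate(self, sigma: float) -> tuple[float, dict]:
        """Return updated alpha and the full state at this sigma."""
        m, lv = self.model, self.level
        alpha_cur = min(max(-sigma / m.site_density, 0.0), 1.0)
        x_cap = potentials.x_capacitance(sigma, m) if lv.use_cap else 0.0
        x_ex = potentials.x_excluded_volume(sigma, m) if lv.use_ex else 0.0
        x_ion = solve_x_ion(
            ContactCondition(sigma=sigma, xi2=m.xi2, betaP=self.betaP),
            self.bath,
            m,
        )
        z_s = potentials.contact_valency(x_ion, self.bath)
        Xi = potentials.coupling_parameter(sigma, z_s, m)
        x_ii = potentials.x_ion_ion(Xi, z_s, m) if lv.use_ii else 0.0
        x_ss = potentials.x_site_site(alpha_cur, m) if lv.use_ss else 0.0
        x_mf = x_ion - x_ii - x_ex
        # the cap switch carries the whole double-layer (mean-field) feedback
        x_site = (x_mf if lv.use_cap else 0.0) + x_cap + x_ss
        alpha = regulation.ionization(self.pH, x_site, m)
        state = {
            "x_ion": x_ion,
            "x_site": x_site,
            "x_mf": x_mf,
            "breakdown": PotentialBreakdown(
                x_cap=x_cap, x_ex=x_ex, x_ss=x_ss, x_ii=x_ii, z_s=z_s, Xi=Xi
            ),
        }
        return alpha, state

    def make_point(
        self, sigma: float, iterations: int, converged: bool
    ) -> SolutionPoint:
        alpha, state = self.evaluate(sigma)
        sigma_out = -alpha * self.model.site_density
        residual = abs(sigma_out - sigma) / self.model.site_density
        return SolutionPoint(
            pH=self.pH,
            alpha=alpha,
            sigma=sigma_out,
            sigma_SI=sigma_to_mC_per_m2(sigma_out),
            x_ion=state["x_ion"],
            x_site=state["x_site"],
            x_mf=state["x_mf"],
            breakdown=state["breakdown"],
            iterations=iterations,
            converged=converged and residual < 1e-10,
            residual=residual,
        )


def solve_point(
    pH: float,
    model: SurfaceModel,
    bath: SaltBath,
    level: LevelSpec = LevelSpec(),
    betaP: float = 0.0,
    options: SolverOptions = SolverOptions(),
    sigma0: float | None = None,
) -> SolutionPoint:
    """Damped fixed-point solution of the charge-regulation state at one pH.

    Starting from the ideal-titration guess (or ``sigma0`` when warm
    starting), iterates sigma_{k+1} = (1-g)*sigma_k + g*(-alpha(sigma_k)
    * sigma_site) with damping g until the update is below tolerance.
    On non-convergence within ``max_iter`` the bisection solver
    :func:`solve_point_bruteforce` is used as a fallback; if that also
    fails the point is returned flagged, never silently.
    """
    ev = _StateEvaluator(pH, model, bath, level, betaP)
    if sigma0 is None:
        sigma = -regulation.henderson_hasselbalch(pH, model) * model.site_density
    else:
        sigma = sigma0
    g = options.damping
    for k in range(1, options.max_iter + 1):
        alpha, _ = ev.evaluate(sigma)
        sigma_new = -alpha * model.site_density
        if abs(sigma_new - sigma) / model.site_density < options.tol:
            return ev.make_point(sigma_new, iterations=k, converged=True)
        sigma = (1.0 - g) * sigma + g * sigma_new
    logger.warning(
        "fixed point not converged at pH %.3g after %d iterations; "
        "falling back to bisection",
        pH,
        options.max_iter,
    )
    fallback = solve_point_bruteforce(pH, model, bath, level, betaP, options)
    return replace(fallback, iterations=options.max_iter + fallback.iterations)


def solve_point_bruteforce(
    pH: float,
    model: SurfaceModel,
    bath: SaltBath,
    level: LevelSpec = LevelSpec(),
    betaP: float = 0.0,
    options: SolverOptions = SolverOptions(),
) -> SolutionPoint:
    """Independent bisection solution of the same fixed point.

    Reformulates self-consistency as the scalar root problem
    f(sigma) = alpha_chem(sigma) + sigma/sigma_site = 0 on
    [-sigma_site, 0]; f(0) > 0 and f(-sigma_site) <= 0, so a bracket
    always exists and Brent's method converges deterministically.
    Serves as an oracle for :func:`solve_point`.
    """
    ev = _StateEvaluator(pH, model, bath, level, betaP)
    n_eval = 0

    def f(sigma: float) -> float:
        nonlocal n_eval
        n_eval += 1
        alpha, _ = ev.evaluate(sigma)
        return alpha + sigma / model.site_density

    lo, hi = -model.site_density, 0.0
    f_hi = f(hi)
    assert f_hi > 0.0, "alpha at zero charge must be positive"
    if f(lo) >= 0.0:  # fully ionized corner (f(lo) == 0 exactly only if alpha = 1)
        sigma_root = lo
    else:
        sigma_root = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=300)
    return ev.make_point(sigma_root, iterations=n_eval, converged=True)


def sweep(
    model: SurfaceModel,
    bath: SaltBath,
    level: LevelSpec = LevelSpec(),
    pH_grid: Sequence[float] = (),
    betaP: float = 0.0,
    options: SolverOptions = SolverOptions(),
) -> TitrationCurve:
    """Titration curve over an ascending pH grid, warm-starting each point
    from the previous solution."""
    grid = list(pH_grid)
    if any(b > a for a, b in zip(grid[1:], grid)):
        raise ValueError("pH grid must be sorted ascending")
    points: list[SolutionPoint] = []
    sigma_prev: float | None = None
    for pH in grid:
        try:
            pt = solve_point(pH, model, bath, level, betaP, options, sigma0=sigma_prev)
        except Exception as exc:
            raise RuntimeError(f"titration failed at pH {pH:g}: {exc}") from exc
        points.append(pt)
        sigma_prev = pt.sigma
    return TitrationCurve(points=tuple(points), model=model, bath=bath, level=level)


def relative_increase(
    curve_num: TitrationCurve, curve_den: TitrationCurve
) -> np.ndarray:
    """Per-pH relative ionization increase of one theory level over another,
    in percent: 100 * (alpha_num/alpha_den - 1).

    Both curves must be on the identical pH grid.
    """
    if len(curve_num) != len(curve_den) or not np.allclose(
        curve_num.pH, curve_den.pH, rtol=0, atol=1e-12
    ):
        raise ValueError("curves are not on the same pH grid")
    return 100.0 * (curve_num.alpha / curve_den.alpha - 1.0)
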