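"""Run configuration: TOML/YAML parsing with strict key validation.

A run document has the sections::

    [surface]   lB_nm, site_density_nm2, pKa, d_is_nm, d_ii_nm, zeta, xi2
    [[salt.species]]  z, conc_M        # one table per ionic species
    [sweep]     pH_min, pH_max, pH_step
    [level]     preset = "a".."d"  OR  cap/ex/ss/ii booleans
    [solver]    tol, max_iter, damping          (optional)
    [pressure]  betaP_nm3                        (optional)

Unknown keys are rejected with their location, so typos never silently
fall back to defaults.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import IonSpecies, SaltBath, SurfaceModel
from .scf import LevelSpec, SolverOptions

__all__ = ["RunConfig", "ExperimentalCurve", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration document failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Validated inputs of one titration run."""

    model: SurfaceModel
    bath: SaltBath
    level: LevelSpec
    pH_grid: tuple[float, ...]
    options: SolverOptions = field(default_factory=SolverOptions)
    betaP: float = 0.0


def _require_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{where}]")


def _parse_document(doc: dict) -> RunConfig:
    _require_keys(doc, {"surface", "salt", "sweep", "level", "solver", "pressure"}, "")

    surf = doc.get("surface", {})
    _require_keys(
        surf,
        {"lB_nm", "site_density_nm2", "pKa", "d_is_nm", "d_ii_nm", "zeta", "xi2"},
        "surface",
    )
    defaults = SurfaceModel()
    try:
        model = SurfaceModel(
            bjerrum_length=surf.get("lB_nm", defaults.bjerrum_length),
            site_density=surf.get("site_density_nm2", defaults.site_density),
            pKa=surf.get("pKa", defaults.pKa),
            d_is=surf.get("d_is_nm", defaults.d_is),
            d_ii=surf.get("d_ii_nm", defaults.d_ii),
            zeta=surf.get("zeta", defaults.zeta),
            xi2=surf.get("xi2", defaults.xi2),
        )
    except ValueError as exc:
        raise ConfigError(f"[surface]: {exc}") from exc

    salt = doc.get("salt", {})
    _require_keys(salt, {"species"}, "salt")
    species_raw = salt.get("species", [])
    if not species_raw:
        raise ConfigError("salt.species must list at least one ionic species")
    species = []
    for i, entry in enumerate(species_raw):
        _require_keys(entry, {"z", "conc_M"}, f"salt.species[{i}]")
        if "z" not in entry or "conc_M" not in entry:
            raise ConfigError(f"salt.species[{i}] needs both 'z' and 'conc_M'")
        species.append(IonSpecies(int(entry["z"]), float(entry["conc_M"])))
    try:
        bath = SaltBath(species=tuple(species))
    except ValueError as exc:
        raise ConfigError(f"salt.species: {exc}") from exc

    sweep_sec = doc.get("sweep", {})
    _require_keys(sweep_sec, {"pH_min", "pH_max", "pH_step"}, "sweep")
    missing = {"pH_min", "pH_max", "pH_step"} - set(sweep_sec)
    if missing:
        raise ConfigError(f"[sweep] is missing {sorted(missing)}")
    lo, hi, step = (float(sweep_sec[k]) for k in ("pH_min", "pH_max", "pH_step"))
    if step <= 0 or hi < lo:
        raise ConfigError("[sweep]: need pH_step > 0 and pH_max >= pH_min")
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    grid = tuple(lo + k * step for k in range(n))

    level_sec = doc.get("level", {})
    _require_keys(level_sec, {"preset", "cap", "ex", "ss", "ii"}, "level")
    if "preset" in level_sec:
        if set(level_sec) != {"preset"}:
            raise ConfigError("[level]: give either 'preset' or explicit toggles, not both")
        try:
            level = LevelSpec.preset(str(level_sec["preset"]))
        except ValueError as exc:
            raise ConfigError(f"[level]: {exc}") from exc
    else:
        level = LevelSpec(
            use_cap=bool(level_sec.get("cap", True)),
            use_ex=bool(level_sec.get("ex", True)),
            use_ss=bool(level_sec.get("ss", True)),
            use_ii=bool(level_sec.get("ii", True)),
        )

    solver_sec = doc.get("solver", {})
    _require_keys(solver_sec, {"tol", "max_iter", "damping"}, "solver")
    opts_defaults = SolverOptions()
    try:
        options = SolverOptions(
            tol=float(solver_sec.get("tol", opts_defaults.tol)),
            max_iter=int(solver_sec.get("max_iter", opts_defaults.max_iter)),
            damping=float(solver_sec.get("damping", opts_defaults.damping)),
        )
    except ValueError as exc:
        raise ConfigError(f"[solver]: {exc}") from exc

    pressure_sec = doc.get("pressure", {})
    _require_keys(pressure_sec, {"betaP_nm3"}, "pressure")
    betaP = float(pressure_sec.get("betaP_nm3", 0.0))

    return RunConfig(
        model=model, bath=bath, level=level, pH_grid=grid, options=options, betaP=betaP
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML (default) or YAML (.yml/.yaml) run document."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() in {".yml", ".yaml"}:
        doc = yaml.safe_load(path.read_text()) or {}
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _parse_document(doc)


@dataclass(frozen=True)
class ExperimentalCurve:
    """An experimental titration curve loaded from delimited text.

    Expects a comma-separated file with '#' comments, a header row, a
    `pH` column and exactly one observable column named either `alpha`
    or `sigma_mC_m2`.
    """

    pH: tuple[float, ...]
    values: tuple[float, ...]
    observable: str  # "alpha" or "sigma_mC_m2"

    @classmethod
    def read(cls, path: str | Path) -> "ExperimentalCurve":
        df = pd.read_csv(path, comment="#")
        if "pH" not in df.columns:
            raise ConfigError(f"{path}: missing required column 'pH'")
        obs_cols = [c for c in df.columns if c in ("alpha", "sigma_mC_m2")]
        if len(obs_cols) != 1:
            raise ConfigError(
                f"{path}: need exactly one observable column "
                f"('alpha' or 'sigma_mC_m2'), found {obs_cols or list(df.columns)}"
            )
        df = df.sort_values("pH")
        pH = df["pH"].to_numpy(dtype=float)
        if np.any(np.diff(pH) <= 0):
            raise ConfigError(f"{path}: pH values must be distinct")
        return cls(
            pH=tuple(pH),
            values=tuple(df[obs_cols[0]].to_numpy(dtype=float)),
            observable=obs_cols[0],
        )
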