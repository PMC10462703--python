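"""Table loaders, config parsing, run manifests and text output.

File formats (all plain delimited text / YAML):

* species table: columns ``name, diffusion_coefficient, units`` with units
  one of ``nm2 ns-1``, ``1e-9 m2 s-1`` (the common tabulation unit; numerically
  identical to nm^2 ns^-1) or ``m2 s-1``.
* reaction table: columns ``reactants, products, rate_constant, rate_units``
  and optional ``aa_convention``.  Reactants/products are semicolon-separated
  species names; an empty reactants cell is a zeroth-order source.  Rate
  units by order: ``M-1 s-1``/``nm3 ns-1`` (second), ``s-1``/``ns-1``
  (first), ``M s-1``/``nm-3 ns-1``/``nm-1 ns-1`` (zeroth).
  ``aa_convention`` applies to A+A reactions: ``per_event`` (default; the
  tabulated k multiplies rho^2 and each event removes two A) or ``halve``
  (the table quotes the observed-loss constant 2k, so k is halved on import).
* G-value table: columns ``species, g_value`` (species per 100 eV).
* scenario config: YAML mapping onto :class:`~spectrakin.radiolysis.ScenarioConfig`
  fields, plus ``species_table``, ``reaction_table``, ``gvalue_table`` paths.

All quantities are converted to the package unit system (nm, ns, Species) at
load time and the conversions are echoed on the module logger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import Reaction, ReactionNetwork, Species
from .radiolysis import ScenarioConfig

__all__ = [
    "load_species",
    "load_reactions",
    "load_network",
    "load_gvalues",
    "load_config",
    "packaged_path",
    "RunManifest",
    "write_table",
]

logger = logging.getLogger("spectrakin")

_AVOGADRO = 6.02214076e23
#: 1 M^-1 s^-1 in nm^3 ns^-1 per molecule pair.
_K2_M_S = 1e24 / _AVOGADRO / 1e9
#: 1 M s^-1 in Species nm^-3 ns^-1.
_K0_M_S = _AVOGADRO / 1e24 / 1e9

_DIFFUSION_FACTORS = {"nm2 ns-1": 1.0, "1e-9 m2 s-1": 1.0, "m2 s-1": 1e9}
_RATE_FACTORS = {
    0: {"nm-1 ns-1": 1.0, "nm-3 ns-1": 1.0, "M s-1": _K0_M_S},
    1: {"ns-1": 1.0, "s-1": 1e-9},
    2: {"nm ns-1": 1.0, "nm3 ns-1": 1.0, "M-1 s-1": _K2_M_S},
}


def packaged_path(name: str) -> Path:
    """Path of a data table shipped with the package (``spectrakin/data``)."""
    return Path(resources.files("spectrakin") / "data" / name)


def _split(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(p.strip() for p in text.split(";") if p.strip())


def load_species(path) -> list[Species]:
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    required = {"name", "diffusion_coefficient", "units"}
    if not required <= set(df.columns):
        raise ValueError(f"species table {path} must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        units = str(row.units).strip()
        if units not in _DIFFUSION_FACTORS:
            raise ValueError(f"unknown diffusion units {units!r} for {row.name}")
        D = float(row.diffusion_coefficient) * _DIFFUSION_FACTORS[units]
        logger.info("species %-8s D = %g %s -> %g nm^2/ns", row.name,
                    row.diffusion_coefficient, units, D)
        out.append(Species(str(row.name).strip(), D))
    return out


def load_reactions(path, species: list[Species]) -> list[Reaction]:
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    required = {"reactants", "products", "rate_constant", "rate_units"}
    if not required <= set(df.columns):
        raise ValueError(f"reaction table {path} must have columns {sorted(required)}")
    known = {s.name for s in species}
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            reactants = _split(row.reactants)
            products = _split(row.products)
            order = len(reactants)
            if order > 2:
                raise ValueError("reaction order above 2")
            units = str(row.rate_units).strip()
            try:
                factor = _RATE_FACTORS[order][units]
            except KeyError:
                raise ValueError(
                    f"rate units {units!r} invalid for an order-{order} reaction"
                ) from None
            k = float(row.rate_constant) * factor
            conv_raw = getattr(row, "aa_convention", None)
            if conv_raw is None or (isinstance(conv_raw, float) and np.isnan(conv_raw)):
                conv = "per_event"
            else:
                conv = str(conv_raw).strip() or "per_event"
            if conv not in ("per_event", "halve"):
                raise ValueError(f"unknown aa_convention {conv!r}")
            if conv == "halve" and order == 2 and len(set(reactants)) == 1:
                k /= 2.0
            for name in (*reactants, *products):
                if name not in known:
                    raise ValueError(f"undeclared species {name!r}")
            label = f"{'+'.join(reactants) or '0'}->{'+'.join(products) or '0'}"
            logger.info("reaction %-22s k = %g %s -> %g (nm/ns system)",
                        label, row.rate_constant, units, k)
            out.append(Reaction(reactants, products, k, label=label))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return out


def load_network(species_path, reactions_path) -> ReactionNetwork:
    """Load and validate a reaction network, converting units to nm/ns."""
    species = load_species(species_path)
    return ReactionNetwork(species, load_reactions(reactions_path, species))


def load_gvalues(path) -> dict[str, float]:
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    if not {"species", "g_value"} <= set(df.columns):
        raise ValueError(f"G-value table {path} needs columns species, g_value")
    return {str(r.species).strip(): float(r.g_value) for r in df.itertuples(index=False)}


def load_config(path) -> tuple[ScenarioConfig, dict]:
    """Parse a YAML scenario config; returns (config, raw mapping).

    Keys matching ScenarioConfig fields populate the dataclass; the raw
    mapping keeps table paths (relative to the config file) and extras like
    sample/snapshot times for the CLI layer.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    names = {f.name for f in dataclasses.fields(ScenarioConfig)}
    kwargs = {k: v for k, v in raw.items() if k in names}
    cfg = ScenarioConfig(**kwargs)
    for key in ("species_table", "reaction_table", "gvalue_table"):
        if key in raw and raw[key] is not None:
            p = Path(raw[key])
            raw[key] = str(p if p.is_absolute() else (path.parent / p))
    return cfg, raw


@dataclass
class RunManifest:
    """Machine-readable record of one run; round-trips losslessly via JSON."""

    config: dict
    tolerances: dict
    accepted_steps: int = 0
    rejected_steps: int = 0
    reached_equilibrium: bool = False
    unit_system: str = "nm, ns, Species"
    software_version: str = ""
    wall_time_s: float | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def write_table(df: pd.DataFrame, path) -> None:
    """Write a delimited-text table with 17 significant digits (so repeated
    runs and convergence reports are bit-stable across platforms)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
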