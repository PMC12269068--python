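"""Chemical model definition: components, species tableau, affinity constants
and charge-distribution (CD) coefficients.

The model is expressed in the classical tableau form used by surface
complexation codes: every species is a linear combination of *components*
(aqueous master ions, reactive surface sites, and abstract surface components
such as the adsorbed-NOM proxy ``HNOM`` or the steric blocker ``S0``), with an
intrinsic formation constant log K and a triplet (dz0, dz1, dz2) distributing
the charge added by the formation reaction over the three electrostatic planes
of the extended Stern layer.

Charge bookkeeping convention
-----------------------------
``dz`` triplets are the charge *added* to each plane by the formation
reaction.  The reference charge of every surface component consumed by the
reaction resides in plane 0, so the physical plane charges of a surface
species are::

    z0 = dz0 + sum(stoich[c] * charge(c) for surface components c)
    z1 = dz1
    z2 = dz2

and dz0 + dz1 + dz2 must equal the total charge of the *aqueous* ions
consumed, which :func:`validate_database` enforces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Component",
    "Species",
    "ModelDatabase",
    "DatabaseError",
    "load_database",
    "save_database",
    "validate_database",
    "default_database",
    "augment_with_steric_sites",
    "load_config",
    "default_config",
]

AQUEOUS_MASTER = "aqueous_master"
SURFACE_SITE = "surface_site"
SURFACE_COMPONENT = "surface_component"
_KINDS = (AQUEOUS_MASTER, SURFACE_SITE, SURFACE_COMPONENT)


class DatabaseError(ValueError):
    """Raised when a model database cannot be parsed or fails validation."""


@dataclass(frozen=True)
class Component:
    """A basis entity of the chemical tableau.

    Parameters
    ----------
    name:
        Unique identifier, e.g. ``"FeOH"``, ``"H"``, ``"HNOM"``.
    kind:
        ``"aqueous_master"``, ``"surface_site"`` or ``"surface_component"``.
    charge:
        Reference charge in valence units (e.g. -0.5 for the singly
        coordinated goethite site FeOH^-0.5, -1 for HNOM^-1).
    site_density:
        Crystallographic site density in sites nm^-2.  Required for
        ``surface_site`` kinds; surface components get their density per
        system (it is a model input, not a mineral property).
    """

    name: str
    kind: str
    charge: float
    site_density: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise DatabaseError(f"component {self.name!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class Species:
    """One row of the tableau: a dissolved or surface species."""

    name: str
    stoichiometry: Mapping[str, float]
    logk: float
    dz0: float = 0.0
    dz1: float = 0.0
    dz2: float = 0.0
    phase: str = "aqueous"  # "aqueous" | "surface"

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def dz(self) -> tuple[float, float, float]:
        return (self.dz0, self.dz1, self.dz2)


@dataclass
class ModelDatabase:
    """A validated collection of components and species."""

    components: list[Component] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    metadata: str = ""

    # identity-based hashing: databases are treated as immutable once built
    __hash__ = object.__hash__
    __eq__ = object.__eq__

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def has_component(self, name: str) -> bool:
        return any(c.name == name for c in self.components)

    def plane_charges(self, sp: Species) -> tuple[float, float, float]:
        """Physical plane charges (z0, z1, z2) of a surface species,
        i.e. the superscript notation of the speciation table."""
        comp = {c.name: c for c in self.components}
        z0 = sp.dz0
        for name, nu in sp.stoichiometry.items():
            c = comp.get(name)
            if c is not None and c.kind in (SURFACE_SITE, SURFACE_COMPONENT):
                z0 += nu * c.charge
        return (z0, sp.dz1, sp.dz2)

    def aqueous_charge(self, sp: Species) -> float:
        """Net charge of an aqueous species from its master-ion makeup."""
        comp = {c.name: c for c in self.components}
        return sum(
            nu * comp[name].charge
            for name, nu in sp.stoichiometry.items()
            if name in comp and comp[name].kind == AQUEOUS_MASTER
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_database(db: ModelDatabase) -> list[str]:
    """Check every tableau invariant; return human-readable violations.

    Violations are data, not exceptions: an empty list means the database is
    valid.  Enforced rules:

    * unique component and species names;
    * surface sites carry a positive site density, aqueous masters none;
    * every stoichiometry entry references a declared component;
    * aqueous species place no charge in the Stern planes and contain no
      surface component;
    * for surface species, dz0+dz1+dz2 equals the summed charge of the
      aqueous ions consumed by the formation reaction;
    * steric mirror species (one ``S0`` added to a parent stoichiometry)
      have log K and dz identical to their parent.
    """
    out: list[str] = []
    comp = {}
    for c in db.components:
        if c.name in comp:
            out.append(f"component {c.name!r}: duplicate name")
        comp[c.name] = c
        if c.kind == SURFACE_SITE:
            if c.site_density is None or c.site_density <= 0:
                out.append(f"component {c.name!r}: surface site needs site_density > 0")
        elif c.kind == AQUEOUS_MASTER and c.site_density is not None:
            out.append(f"component {c.name!r}: aqueous master must not have site_density")
        elif c.kind == SURFACE_COMPONENT and c.site_density is not None and c.site_density <= 0:
            out.append(f"component {c.name!r}: site_density must be positive when given")

    seen = set()
    by_stoich: dict[tuple, Species] = {}
    for s in db.species:
        if s.name in seen:
            out.append(f"species {s.name!r}: duplicate name")
        seen.add(s.name)
        unknown = [n for n in s.stoichiometry if n not in comp]
        for n in unknown:
            out.append(f"species {s.name!r}: references unknown component {n!r}")
        if unknown:
            continue
        surf = [n for n, nu in s.stoichiometry.items()
                if nu and comp[n].kind in (SURFACE_SITE, SURFACE_COMPONENT)]
        if s.phase == "aqueous":
            if surf:
                out.append(f"species {s.name!r}: aqueous phase but contains surface "
                           f"component(s) {surf}")
            if s.dz != (0.0, 0.0, 0.0):
                out.append(f"species {s.name!r}: aqueous species must have dz0=dz1=dz2=0")
        else:
            if not surf:
                out.append(f"species {s.name!r}: surface phase but no surface component")
            zaq = sum(nu * comp[n].charge for n, nu in s.stoichiometry.items()
                      if comp[n].kind == AQUEOUS_MASTER)
            if abs((s.dz0 + s.dz1 + s.dz2) - zaq) > 1e-9:
                out.append(
                    f"species {s.name!r}: dz0+dz1+dz2 = {s.dz0 + s.dz1 + s.dz2:g} but the "
                    f"reaction adds {zaq:g} charge from aqueous ions")
        key = tuple(sorted((n, nu) for n, nu in s.stoichiometry.items() if nu))
        by_stoich[key] = s

    # steric mirrors must be exact copies of their parent
    for s in db.species:
        nu_s = s.stoichiometry.get("S0", 0)
        if nu_s != 1 or any(n not in comp for n in s.stoichiometry):
            continue
        parent_key = tuple(sorted(
            (n, nu) for n, nu in s.stoichiometry.items() if nu and n != "S0"))
        parent = by_stoich.get(parent_key)
        if parent is None or parent is s:
            continue
        if abs(parent.logk - s.logk) > 1e-12 or parent.dz != s.dz:
            out.append(
                f"species {s.name!r}: steric mirror of {parent.name!r} must copy its "
                f"logK and dz exactly")
    return out


def _require_valid(db: ModelDatabase) -> ModelDatabase:
    bad = validate_database(db)
    if bad:
        raise DatabaseError("invalid model database:\n  " + "\n  ".join(bad))
    return db


# ---------------------------------------------------------------------------
# Tableau file I/O
# ---------------------------------------------------------------------------

_RESERVED = {"complex", "name", "dz0", "dz1", "dz2", "logK", "logk"}


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    xf = float(x)
    return str(int(xf)) if xf.is_integer() else str(xf)


def load_database(path: str | Path, format: str = "tableau-tsv") -> ModelDatabase:
    """Read a model database from disk.

    Two on-disk dialects are supported: ``tableau-tsv``, a two-section
    tab-separated file whose species header mirrors the speciation-table
    layout (complex, component columns..., dz0, dz1, dz2, logK), and
    ``structured-text``, a JSON serialization of the same content.
    Round-trips with :func:`save_database`.
    """
    path = Path(path)
    text = path.read_text()
    if format == "structured-text":
        return _from_json(text)
    if format != "tableau-tsv":
        raise DatabaseError(f"unknown format {format!r}")

    meta_lines: list[str] = []
    components: list[Component] = []
    species: list[Species] = []
    section = None
    header: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            meta_lines.append(line.lstrip("# ").rstrip())
            continue
        low = line.strip().lower()
        if low == "[components]":
            section, header = "components", None
            continue
        if low == "[species]":
            section, header = "species", None
            continue
        if section is None:
            raise DatabaseError(f"{path}:{lineno}: content before any [components]/[species] section")
        cells = [c.strip() for c in line.split("\t")]
        if header is None:
            header = cells
            continue
        try:
            if section == "components":
                row = dict(zip(header, cells))
                sd = row.get("site_density", "")
                components.append(Component(
                    name=row["name"], kind=row["kind"], charge=float(row["charge"]),
                    site_density=float(sd) if sd else None))
            else:
                row = dict(zip(header, cells))
                name_col = "complex" if "complex" in row else "name"
                stoich = {h: float(row[h]) for h in header
                          if h not in _RESERVED and row.get(h, "") != ""}
                stoich = {k: v for k, v in stoich.items() if v != 0}
                comp_kinds = {c.name: c.kind for c in components}
                surf = any(comp_kinds.get(n) in (SURFACE_SITE, SURFACE_COMPONENT)
                           for n in stoich)
                species.append(Species(
                    name=row[name_col], stoichiometry=stoich,
                    logk=float(row.get("logK", row.get("logk", "0"))),
                    dz0=float(row.get("dz0", 0) or 0), dz1=float(row.get("dz1", 0) or 0),
                    dz2=float(row.get("dz2", 0) or 0),
                    phase="surface" if surf else "aqueous"))
        except (KeyError, ValueError) as exc:
            raise DatabaseError(f"{path}:{lineno}: cannot parse row: {exc}") from exc

    db = ModelDatabase(components=components, species=species, metadata="\n".join(meta_lines))
    return _require_valid(db)


def save_database(db: ModelDatabase, path: str | Path, format: str = "tableau-tsv") -> None:
    """Write a database in the canonical form read back by :func:`load_database`."""
    path = Path(path)
    if format == "structured-text":
        path.write_text(_to_json(db))
        return
    if format != "tableau-tsv":
        raise DatabaseError(f"unknown format {format!r}")
    lines: list[str] = [f"# {m}" for m in db.metadata.splitlines() if m]
    lines.append("[components]")
    lines.append("name\tkind\tcharge\tsite_density")
    for c in db.components:
        lines.append("\t".join([c.name, c.kind, _fmt(c.charge), _fmt(c.site_density)]).rstrip("\t"))
    lines.append("[species]")
    comp_cols = [c.name for c in db.components]
    lines.append("\t".join(["complex", *comp_cols, "dz0", "dz1", "dz2", "logK"]))
    for s in db.species:
        row = [s.name]
        row += [_fmt(s.stoichiometry.get(c, 0)) if s.stoichiometry.get(c, 0) else "0"
                for c in comp_cols]
        row += [_fmt(s.dz0), _fmt(s.dz1), _fmt(s.dz2), _fmt(s.logk)]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _to_json(db: ModelDatabase) -> str:
    return json.dumps({
        "metadata": db.metadata,
        "components": [
            {"name": c.name, "kind": c.kind, "charge": c.charge,
             "site_density": c.site_density} for c in db.components],
        "species": [
            {"name": s.name, "stoichiometry": dict(s.stoichiometry), "logK": s.logk,
             "dz": [s.dz0, s.dz1, s.dz2], "phase": s.phase} for s in db.species],
    }, indent=1)


def _from_json(text: str) -> ModelDatabase:
    try:
        d = json.loads(text)
        db = ModelDatabase(
            components=[Component(**c) for c in d["components"]],
            species=[Species(name=s["name"], stoichiometry=s["stoichiometry"],
                             logk=s["logK"], dz0=s["dz"][0], dz1=s["dz"][1],
                             dz2=s["dz"][2], phase=s["phase"])
                     for s in d["species"]],
            metadata=d.get("metadata", ""))
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise DatabaseError(f"cannot parse structured-text database: {exc}") from exc
    return _require_valid(db)


# ---------------------------------------------------------------------------
# Configuration of non-tableau constants
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Load the shipped configuration of model constants.

    The shipped file carries all constants that are not part of the printed
    speciation table, each with a provenance note (goethite PZC and Stern
    capacitances, electrolyte pair constants, triply coordinated site density,
    glyphosate aqueous and surface binding constants, the adsorbed-NOM
    protonation constant).  Everything in it can be overridden per call.
    """
    with resources.files("snomcd.data").joinpath("defaults.json").open() as fh:
        return json.load(fh)


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge the shipped defaults with an optional JSON/TOML file and
    explicit overrides (highest precedence)."""
    cfg = default_config()
    if path is not None:
        p = Path(path)
        if p.suffix.lower() == ".toml":
            import tomllib
            user = tomllib.loads(p.read_text())
        else:
            user = json.loads(p.read_text())
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    return cfg


# ---------------------------------------------------------------------------
# The goethite / PMG / NOM / steric database
# ---------------------------------------------------------------------------

def default_database(config: Mapping | None = None, *, include_steric: bool = True,
                     include_pmg: bool = True, include_nom: bool = True) -> ModelDatabase:
    """Build the working goethite-PMG-NOM-steric database.

    Speciation-table values (site protonation log K = PZC 9.3, the three NOM
    surface species with log K 0 / log K_H / 0.6 and their CD triplets, the
    singly coordinated site density 3.45 nm^-2) are fixed here; every other
    constant comes from the configuration (see :func:`default_config`), so
    literature-sourced values stay swappable without touching code.
    """
    cfg = dict(default_config())
    if config:
        cfg.update(config)

    missing = [k for k in ("pzc_logk", "triply_site_density", "na_pair_logk",
                           "no3_pair_dlogk", "fenomh_logk_h", "pmg_aqueous_logk",
                           "pmg_surface_species") if k not in cfg]
    if missing:
        raise DatabaseError(f"configuration is missing required key(s): {missing}")

    pzc = float(cfg["pzc_logk"])
    comps = [
        Component("H", AQUEOUS_MASTER, 1.0),
        Component("Na", AQUEOUS_MASTER, 1.0),
        Component("NO3", AQUEOUS_MASTER, -1.0),
        Component("FeOH", SURFACE_SITE, -0.5, site_density=float(cfg.get("singly_site_density", 3.45))),
        Component("Fe3O", SURFACE_SITE, -0.5, site_density=float(cfg["triply_site_density"])),
    ]
    if include_pmg:
        comps.insert(3, Component("PMG", AQUEOUS_MASTER, -3.0))
    if include_nom:
        comps.append(Component("HNOM", SURFACE_COMPONENT, -1.0))
    if include_steric:
        comps.append(Component("S0", SURFACE_COMPONENT, 0.0))

    sp: list[Species] = [
        Species("H+", {"H": 1}, 0.0),
        Species("OH-", {"H": -1}, float(cfg.get("logk_water", -14.0))),
        Species("Na+", {"Na": 1}, 0.0),
        Species("NO3-", {"NO3": 1}, 0.0),
    ]
    if include_pmg:
        sp.append(Species("PMG-3", {"PMG": 1}, 0.0))
        for i, lk in enumerate(cfg["pmg_aqueous_logk"], start=1):
            charge = -3 + i
            tag = f"{'+' if charge > 0 else ''}{charge}" if charge else "0"
            sp.append(Species(f"H{i}PMG{tag}", {"PMG": 1, "H": i}, float(lk)))

    na_lk = float(cfg["na_pair_logk"])
    no3_lk = pzc + float(cfg["no3_pair_dlogk"])
    for site in ("FeOH", "Fe3O"):
        sp += [
            Species(site, {site: 1}, 0.0, phase="surface"),
            Species(f"{site}2" if site == "FeOH" else f"{site}H",
                    {site: 1, "H": 1}, pzc, dz0=1, phase="surface"),
            Species(f"{site}-Na", {site: 1, "Na": 1}, na_lk, dz1=1, phase="surface"),
            Species(f"{site}{'2' if site == 'FeOH' else 'H'}-NO3",
                    {site: 1, "H": 1, "NO3": 1}, no3_lk, dz0=1, dz1=-1, phase="surface"),
        ]
    if include_nom:
        sp += [
            Species("FeNOM", {"FeOH": 1, "HNOM": 1}, 0.0,
                    dz0=1.5, dz1=-1.0, dz2=-0.5, phase="surface"),
            Species("FeNOMH", {"FeOH": 1, "HNOM": 1, "H": 1},
                    float(cfg["fenomh_logk_h"]), dz0=1.5, dz1=-0.5, dz2=0.0,
                    phase="surface"),
            Species("FeOH2-NOM", {"FeOH": 1, "HNOM": 1}, 0.6,
                    dz0=2.0, dz1=-1.5, dz2=-0.5, phase="surface"),
        ]
    if include_pmg:
        for row in cfg["pmg_surface_species"]:
            sp.append(Species(row["name"],
                              {"FeOH": row["n_feoh"], "PMG": 1, "H": row["n_h"]},
                              float(row["logK"]), dz0=float(row["dz"][0]),
                              dz1=float(row["dz"][1]), dz2=float(row["dz"][2]),
                              phase="surface"))

    db = ModelDatabase(components=comps, species=sp,
                       metadata="goethite-PMG-NOM steric CD database")
    _require_valid(db)
    if include_steric:
        db = augment_with_steric_sites(db)
    return db


def augment_with_steric_sites(db: ModelDatabase) -> ModelDatabase:
    """Add steric mirror species for every non-hindered FeOH species.

    For each species formed from the singly coordinated site by protons or
    electrolyte ions only (not NOM, not PMG — those are the sterically
    hindered adsorbates), a mirror with one ``S0`` added to the stoichiometry
    and *identical* log K and CD coefficients is created.  Blocked sites
    thereby keep their full proton/electrolyte chemistry — the primary
    charging of the surface is untouched — while being unavailable to PMG.
    """
    if not db.has_component("S0"):
        raise DatabaseError("cannot augment: component 'S0' absent from database")
    hindered = {"HNOM", "PMG", "S0"}
    mirrors: list[Species] = []
    for s in db.species:
        if s.phase != "surface" or not s.stoichiometry.get("FeOH"):
            continue
        if any(s.stoichiometry.get(h) for h in hindered):
            continue
        stoich = dict(s.stoichiometry)
        stoich["S0"] = 1
        mirrors.append(replace(s, name=f"S-{s.name}", stoichiometry=stoich))
    out = ModelDatabase(components=list(db.components),
                        species=list(db.species) + mirrors,
                        metadata=db.metadata)
    return _require_valid(out)


def table1_path() -> Path:
    """Path of the shipped illustrative speciation tableau fixture."""
    return Path(str(resources.files("snomcd.data").joinpath("table1.tsv")))
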