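"""Synthetic competitive-adsorption datasets.

Emulates the experimental design of the reference study — HA-goethite
composites at several HA loadings and target pH values in NaNO3 background,
each probed with a 9-step PMG dilution series — so that the full pipeline,
including parameter fitting, is exercisable without any external data.
Observations are the model's own dissolved-PMG predictions perturbed with
log-normal measurement noise and censored at a limit of detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .batch import BatchSystem, simulate_isotherm
from .model_db import ModelDatabase, default_config, default_database
from .nomcd_steric import NomCdParams, StericParams
from .speciation import SolverOptions

__all__ = [
    "DesignSpec",
    "SyntheticPoint",
    "SyntheticDataset",
    "generate_design",
    "reference_design",
    "simulate_observations",
]

#: PMG stock volumes as fractions of the 1 mL final volume (dilution series)
STOCK_FRACTIONS = (0.50, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05)


@dataclass(frozen=True)
class DesignSpec:
    """Factor levels of a synthetic batch design.

    Defaults mirror the study conditions: HA loadings 0.5-1.6 mg m^-2,
    target pH 4-8 with per-point jitter bounded so each isotherm spans at
    most 0.3 pH units, NaNO3 at 0.1 / 0.01 M, a 1.45 mM PMG stock dosed at
    0.05-0.50 of the final volume (top total 0.725 mM), 10 g L^-1 goethite
    of 94 m^2 g^-1.
    """

    ha_levels: tuple[float, ...] = (0.5, 1.1, 1.3, 1.6)
    ph_targets: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0, 8.0)
    ionic_strengths: tuple[float, ...] = (0.1, 0.01)
    pmg_stock: float = 1.45e-3
    stock_volumes: tuple[float, ...] = STOCK_FRACTIONS
    goethite: float = 10.0
    ssa: float = 94.0
    ph_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ph_jitter < 0 or self.ph_jitter > 0.5:
            raise ValueError("ph_jitter must lie in [0, 0.5]")
        if min(self.ha_levels) < 0 or min(self.ionic_strengths) <= 0 \
                or min(self.stock_volumes) <= 0 or self.pmg_stock <= 0:
            raise ValueError("levels must be positive")


@dataclass(frozen=True)
class SyntheticPoint:
    system: BatchSystem
    true_dissolved: float
    observed_dissolved: float
    censored: bool


@dataclass
class SyntheticDataset:
    """Points plus the ground truth they were generated from."""

    points: list[SyntheticPoint]
    truth: dict[str, float]
    noise_sigma: float
    lod: float
    seed: int

    @property
    def n_usable(self) -> int:
        return sum(not p.censored for p in self.points)

    def fit_data(self) -> list[tuple[BatchSystem, float]]:
        """(system, observed) pairs for :func:`snomcd.batch.fit_parameters`
        (censored points carry observations below the LOD and are excluded
        there)."""
        return [(p.system, p.observed_dissolved) for p in self.points]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "pH": p.system.ph, "ionic_strength_M": p.system.ionic_strength,
            "goethite_g_L": p.system.goethite_conc, "ssa_m2_g": p.system.ssa,
            "ha_loading_mg_m2": p.system.ha_loading,
            "pmg_total_M": p.system.pmg_total,
            "pmg_dissolved_M": p.observed_dissolved,
            "true_dissolved_M": p.true_dissolved,
            "censored": p.censored,
        } for p in self.points]
        return pd.DataFrame(rows)


def _isotherm_systems(ha: float, ph_target: float, ionic: float,
                      spec: DesignSpec, rng: np.random.Generator) -> list[BatchSystem]:
    half = spec.ph_jitter / 2.0
    systems = []
    for frac in spec.stock_volumes:
        ph = ph_target + rng.uniform(-half, half)
        systems.append(BatchSystem(
            ph=ph, ionic_strength=ionic, pmg_total=spec.pmg_stock * frac,
            ha_loading=ha, goethite_conc=spec.goethite, ssa=spec.ssa))
    return systems


def generate_design(spec: DesignSpec) -> list[BatchSystem]:
    """Full crossing of HA level x ionic strength x target pH, one 9-point
    PMG dilution series per cell, with reproducible per-point pH jitter."""
    rng = np.random.default_rng(spec.seed)
    out: list[BatchSystem] = []
    for ha in spec.ha_levels:
        for ionic in spec.ionic_strengths:
            for ph_t in spec.ph_targets:
                out.extend(_isotherm_systems(ha, ph_t, ionic, spec, rng))
    return out


def reference_design(seed: int = 0, spec: DesignSpec | None = None) -> list[BatchSystem]:
    """The 16-isotherm layout of the reference experiments (144 points).

    High HA at 1.6 mg m^-2 (pH 4, 5, 6) and 1.3 mg m^-2 (pH 7, 8),
    intermediate 1.1 mg m^-2 (pH 4-8), low 0.5 mg m^-2 (pH 4, 6, 8), all in
    0.1 M NaNO3; the low-HA series repeated at 0.01 M.
    """
    spec = spec or DesignSpec(seed=seed)
    rng = np.random.default_rng(seed)
    layout = (
        [(1.6, ph, 0.1) for ph in (4.0, 5.0, 6.0)]
        + [(1.3, ph, 0.1) for ph in (7.0, 8.0)]
        + [(1.1, ph, 0.1) for ph in (4.0, 5.0, 6.0, 7.0, 8.0)]
        + [(0.5, ph, 0.1) for ph in (4.0, 6.0, 8.0)]
        + [(0.5, ph, 0.01) for ph in (4.0, 6.0, 8.0)]
    )
    out: list[BatchSystem] = []
    for ha, ph_t, ionic in layout:
        out.extend(_isotherm_systems(ha, ph_t, ionic, spec, rng))
    return out


def simulate_observations(design: Sequence[BatchSystem],
                          truth_nom: NomCdParams | None = None,
                          truth_steric: StericParams | None = None,
                          noise_sigma: float = 0.2,
                          lod: float | None = None,
                          seed: int = 0,
                          db: ModelDatabase | None = None,
                          options: SolverOptions | None = None,
                          config: dict | None = None) -> SyntheticDataset:
    """Generate observations: solve every design point at the truth
    parameters, perturb log10 dissolved PMG with N(0, sigma^2) noise, censor
    below the LOD.  Same seed, same dataset, bit for bit."""
    cfg = config or default_config()
    if lod is None:
        lod = float(cfg.get("lod_M", 6e-7))
    truth_nom = truth_nom or NomCdParams()
    truth_steric = truth_steric or StericParams()
    db = db or default_database(cfg)

    pts = simulate_isotherm(design, db, truth_nom, truth_steric,
                            options=options, config=cfg)
    if len(pts) != len(design):
        raise RuntimeError("solver failures while generating synthetic truth")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sigma, size=len(pts)) if noise_sigma > 0 \
        else np.zeros(len(pts))
    points = []
    for p, e in zip(pts, eps):
        true = p.pmg_dissolved
        obs = 10.0 ** (np.log10(max(true, 1e-300)) + e) if true > 0 else 0.0
        points.append(SyntheticPoint(
            system=p.system, true_dissolved=true, observed_dissolved=float(obs),
            censored=bool(obs < lod)))
    return SyntheticDataset(
        points=points,
        truth={"s_max": truth_steric.s_max, "fenomt": truth_nom.fenomt},
        noise_sigma=noise_sigma, lod=lod, seed=seed)
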