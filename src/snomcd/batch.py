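"""Batch competitive-adsorption systems: per-point speciation, isotherms,
interface statistics and parameter fitting.

A :class:`BatchSystem` describes one experimental point (goethite suspension,
pH, ionic strength, HA loading, total PMG).  :func:`simulate_point` turns it
into an equilibrium problem — HNOM density from the HA loading, steric
blocker density from theta_S — and returns dissolved/adsorbed PMG plus the
NOM interface statistics.  :func:`fit_parameters` estimates S_max^0 (and
optionally FeNOM_T) by bounded least squares on log10 dissolved PMG, the
objective the reference study uses (RMSE on the logarithm of the solution
concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .model_db import ModelDatabase, default_config, default_database
from .nomcd_steric import (
    NomCdParams,
    StericParams,
    hnom_surface_density,
    s0_surface_density,
    theta_s,
)
from .speciation import (
    EDLParameters,
    SolverOptions,
    SpeciationError,
    SpeciationResult,
    SystemComposition,
    solve_equilibrium,
)

__all__ = [
    "BatchSystem",
    "IsothermPoint",
    "FitResult",
    "default_edl_parameters",
    "simulate_point",
    "simulate_isotherm",
    "nom_interface_stats",
    "rmse_log10",
    "fit_parameters",
]

NOM_SPECIES_INNER = ("FeNOM", "FeNOMH")
NOM_SPECIES_OUTER = ("FeOH2-NOM",)


@dataclass(frozen=True)
class BatchSystem:
    """One batch adsorption system (all concentrations at equilibrium volume)."""

    ph: float
    ionic_strength: float          # mol L^-1
    pmg_total: float               # mol L^-1
    ha_loading: float = 0.0        # mg HA m^-2 (Gamma_NOM)
    goethite_conc: float = 10.0    # g L^-1
    ssa: float = 94.0              # m^2 g^-1

    def __post_init__(self) -> None:
        if self.goethite_conc <= 0 or self.ssa <= 0:
            raise ValueError("goethite_conc and ssa must be > 0")
        if self.ha_loading < 0 or self.pmg_total < 0:
            raise ValueError("ha_loading and pmg_total must be >= 0")
        if not 2.0 <= self.ph <= 12.0:
            raise ValueError("pH out of the supported 2-12 range")


@dataclass
class IsothermPoint:
    """Model output for one batch system."""

    system: BatchSystem
    pmg_dissolved: float           # mol L^-1
    pmg_adsorbed: float            # umol m^-2
    nom_outer_sphere_fraction: float | None
    r_ratio: float | None
    theta: float = 0.0             # theta_S used
    s0: float = 0.0                # umol m^-2
    hnom: float = 0.0              # umol m^-2
    speciation: SpeciationResult | None = None


@dataclass
class FitResult:
    """Least-squares estimate(s) with linearized 95% CI and fit quality."""

    estimates: dict[str, float]
    ci95: dict[str, float]         # half-widths
    rmse: float                    # log10 units
    r_squared: float
    n: int
    at_bound: list[str] = field(default_factory=list)
    objective_trace: list[tuple[tuple[float, ...], float]] = field(default_factory=list)


def default_edl_parameters(sys: BatchSystem, config: dict | None = None) -> EDLParameters:
    """Stern capacitances from the configuration, geometry from the system."""
    cfg = config or default_config()
    return EDLParameters(c1=float(cfg["c1_F_m2"]), c2=float(cfg["c2_F_m2"]),
                         specific_surface_area=sys.ssa,
                         solid_concentration=sys.goethite_conc)


def simulate_point(sys: BatchSystem, db: ModelDatabase,
                   nom: NomCdParams | None = None,
                   steric: StericParams | None = None,
                   edlp: EDLParameters | None = None,
                   options: SolverOptions | None = None,
                   warm_start: SpeciationResult | None = None,
                   config: dict | None = None) -> IsothermPoint:
    """Solve one batch system.

    The HNOM total follows from the HA loading (linear in Gamma_NOM) and the
    steric blocker total from theta_S(pH, I) * S_max^0; both are injected as
    surface-component totals before the equilibrium solve.  Solver errors are
    re-raised annotated with the point's conditions.
    """
    nom = nom or NomCdParams()
    steric = steric or StericParams()
    if edlp is None:
        edlp = default_edl_parameters(sys, config)
    else:
        edlp = EDLParameters(c1=edlp.c1, c2=edlp.c2,
                             specific_surface_area=sys.ssa,
                             solid_concentration=sys.goethite_conc)

    hnom = hnom_surface_density(sys.ha_loading, nom)          # umol m^-2
    th = theta_s(10.0 ** -sys.ph, sys.ionic_strength, steric)
    s0 = s0_surface_density(th, steric.s_max)                  # umol m^-2

    totals: dict[str, float] = {
        "Na": sys.ionic_strength,
        "NO3": sys.ionic_strength,
    }
    if sys.pmg_total > 0:
        totals["PMG"] = sys.pmg_total
    if hnom > 0 and db.has_component("HNOM"):
        totals["HNOM"] = hnom * 1e-6
    if s0 > 0 and db.has_component("S0"):
        totals["S0"] = s0 * 1e-6
    comp = SystemComposition(totals=totals,
                             fixed_activities={"H": 10.0 ** -sys.ph},
                             ionic_strength=sys.ionic_strength)
    try:
        res = solve_equilibrium(db, comp, edlp, options, warm_start=warm_start)
    except SpeciationError as exc:
        raise type(exc)(
            f"{exc} [pH={sys.ph:.2f}, I={sys.ionic_strength:g} M, "
            f"PMG={sys.pmg_total:.3e} M, HA={sys.ha_loading:g} mg/m2]") from exc

    dissolved = res.total_aqueous("PMG", db) if sys.pmg_total > 0 else 0.0
    adsorbed = res.total_adsorbed("PMG", db) * 1e6 if sys.pmg_total > 0 else 0.0
    fos, r = nom_interface_stats(res)
    return IsothermPoint(system=sys, pmg_dissolved=dissolved, pmg_adsorbed=adsorbed,
                         nom_outer_sphere_fraction=fos, r_ratio=r,
                         theta=th, s0=s0, hnom=hnom, speciation=res)


def simulate_isotherm(systems: Sequence[BatchSystem], db: ModelDatabase,
                      nom: NomCdParams | None = None,
                      steric: StericParams | None = None,
                      edlp: EDLParameters | None = None,
                      options: SolverOptions | None = None,
                      config: dict | None = None) -> list[IsothermPoint]:
    """Solve a series of systems, each at its own pH, preserving order.

    Consecutive solutions warm-start each other.  Per-point failures are
    collected; the call fails only when every point fails.
    """
    if not systems:
        raise ValueError("empty system list")
    out: list[IsothermPoint] = []
    errors: list[Exception] = []
    warm: SpeciationResult | None = None
    for sys in systems:
        try:
            pt = simulate_point(sys, db, nom, steric, edlp, options,
                                warm_start=warm, config=config)
            warm = pt.speciation
            out.append(pt)
        except SpeciationError as exc:  # retry cold before recording failure
            try:
                pt = simulate_point(sys, db, nom, steric, edlp, options, config=config)
                warm = pt.speciation
                out.append(pt)
            except SpeciationError as exc2:
                errors.append(exc2)
                warm = None
    if not out:
        raise SpeciationError(
            f"all {len(systems)} points failed; first error: {errors[0]}")
    if errors:
        import warnings
        warnings.warn(f"{len(errors)} of {len(systems)} isotherm points failed "
                      f"to converge and were dropped", stacklevel=2)
    return out


def nom_interface_stats(point: IsothermPoint | SpeciationResult) -> tuple[float | None, float | None]:
    """Outer-sphere NOM fraction and the carboxyl distribution ratio R.

    f_OS = [FeOH2-NOM] / ([FeNOM] + [FeNOMH] + [FeOH2-NOM]); R = 0.5 (1 -
    f_OS), spanning 0.5 for fully inner-sphere NOM (half of each HNOM's two
    carboxylates in the first Stern layer) down to 0 for fully outer-sphere.
    Returns (None, None) when no NOM is present.
    """
    res = point.speciation if isinstance(point, IsothermPoint) else point
    if res is None:
        return (None, None)
    amounts = res.species_amounts
    inner = sum(amounts.get(n, 0.0) for n in NOM_SPECIES_INNER)
    outer = sum(amounts.get(n, 0.0) for n in NOM_SPECIES_OUTER)
    tot = inner + outer
    if tot <= 0:
        return (None, None)
    fos = outer / tot
    return (fos, 0.5 * (1.0 - fos))


def rmse_log10(model: Iterable[float], observed: Iterable[float]) -> float:
    """Root-mean-square error between log10 of two positive series."""
    m = np.asarray(list(model), dtype=float)
    o = np.asarray(list(observed), dtype=float)
    if m.shape != o.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {o.shape}")
    if m.size == 0:
        raise ValueError("empty series")
    if np.any(m <= 0) or np.any(o <= 0):
        raise ValueError("all values must be > 0 (censor below-LOD points upstream)")
    return float(np.sqrt(np.mean((np.log10(m) - np.log10(o)) ** 2)))


_BOUNDS = {"s_max": (0.0, 6.0), "fenomt": (0.1, 5.0)}
_NEUTRAL_START = {"s_max": 3.0, "fenomt": 1.77}


def fit_parameters(data: Sequence[tuple[BatchSystem, float]],
                   free: Sequence[str] = ("s_max",),
                   db: ModelDatabase | None = None,
                   nom: NomCdParams | None = None,
                   steric: StericParams | None = None,
                   options: SolverOptions | None = None,
                   config: dict | None = None,
                   lod: float | None = None,
                   multistart: int = 1) -> FitResult:
    """Estimate S_max^0 (and optionally FeNOM_T) from observed dissolved PMG.

    Bounded least squares (trust-region reflective) on residuals
    log10(model) - log10(observed); observations below the LOD are excluded.
    95% CI from the linearized covariance s^2 (J^T J)^-1 with a t quantile.
    With ``multistart`` > 1 the best of several deterministic starts across
    the bounds is kept (ties broken by lower RMSE, then lower s_max).
    """
    free = list(free)
    bad = [f for f in free if f not in _BOUNDS]
    if bad:
        raise ValueError(f"unknown free parameter(s) {bad}; choose from {sorted(_BOUNDS)}")
    cfg = config or default_config()
    if lod is None:
        lod = float(cfg.get("lod_M", 6e-7))
    db = db or default_database(cfg)
    nom = nom or NomCdParams()
    steric = steric or StericParams()

    usable = [(s, o) for s, o in data if o is not None and o > lod]
    n = len(usable)
    if n < 2 * len(free):
        raise ValueError(
            f"only {n} observations above the LOD ({lod:g} M); need at least "
            f"{2 * len(free)} to fit {free}")
    systems = [s for s, _ in usable]
    obs_log = np.log10([o for _, o in usable])
    trace: list[tuple[tuple[float, ...], float]] = []

    def residuals(x: np.ndarray) -> np.ndarray:
        st = replace(steric, s_max=float(x[free.index("s_max")])) \
            if "s_max" in free else steric
        nm = replace(nom, fenomt=float(x[free.index("fenomt")])) \
            if "fenomt" in free else nom
        pts = simulate_isotherm(systems, db, nm, st, options=options, config=cfg)
        if len(pts) != n:
            raise SpeciationError("point failures during fitting")
        model = np.array([max(p.pmg_dissolved, 1e-300) for p in pts])
        r = np.log10(model) - obs_log
        trace.append((tuple(float(v) for v in x), float(np.sqrt(np.mean(r ** 2)))))
        return r

    lo = np.array([_BOUNDS[f][0] for f in free])
    hi = np.array([_BOUNDS[f][1] for f in free])
    starts = [np.array([_NEUTRAL_START[f] for f in free])]
    if multistart > 1:
        for frac in np.linspace(0.15, 0.85, multistart - 1):
            starts.append(lo + frac * (hi - lo))

    best = None
    for x0 in starts:
        sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                     method="trf", xtol=1e-10, ftol=1e-12,
                                     diff_step=1e-3)
        key = (round(float(np.sqrt(2 * sol.cost / n)), 12),
               float(sol.x[free.index("s_max")]) if "s_max" in free else 0.0)
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]

    r = sol.fun
    rmse = float(np.sqrt(np.mean(r ** 2)))
    dof = max(n - len(free), 1)
    s2 = float(np.sum(r ** 2)) / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(free), np.nan)
    tq = float(stats.t.ppf(0.975, dof))
    ci = {f: tq * float(se[i]) for i, f in enumerate(free)}
    ss_tot = float(np.sum((obs_log - obs_log.mean()) ** 2))
    r2 = 1.0 - float(np.sum(r ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    at_bound = [f for i, f in enumerate(free)
                if math.isclose(sol.x[i], lo[i], abs_tol=1e-9)
                or math.isclose(sol.x[i], hi[i], abs_tol=1e-9)]
    return FitResult(
        estimates={f: float(sol.x[i]) for i, f in enumerate(free)},
        ci95=ci, rmse=rmse, r_squared=r2, n=n, at_bound=at_bound,
        objective_trace=trace)
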