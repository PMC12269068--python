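"""Multicomponent chemical equilibrium with extended-Stern electrostatics.

Solves mass action + mass/site balances + the three-plane (0/1/2) charge-
potential relations of the extended Stern layer in one damped Newton
iteration.  Unknowns are the log10 free activities of the non-fixed
components plus the log10 Boltzmann factors of the three electrostatic
planes; the diffuse layer is closed with the Gouy-Chapman relation at the
head-of-diffuse-layer plane (plane 2).

Conventions
-----------
* aqueous amounts in mol L^-1, surface amounts internally in mol L^-1 of
  suspension (mol m^-2 x specific surface area x solid concentration) and
  reported back in mol m^-2;
* plane charge of a surface species = its dz triplet plus the reference
  charge of its surface components, placed in plane 0;
* activity corrections by the Davies equation (0.3 linear term), applied to
  aqueous species only; surface "activities" are concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_db import (
    AQUEOUS_MASTER,
    SURFACE_COMPONENT,
    SURFACE_SITE,
    ModelDatabase,
)

__all__ = [
    "EDLParameters",
    "EDLState",
    "SystemComposition",
    "SpeciationResult",
    "SolverOptions",
    "SpeciationError",
    "ConvergenceError",
    "InfeasibleSystemError",
    "davies_log_gamma",
    "gouy_chapman_sigma",
    "solve_equilibrium",
]

# physical constants, 25 C
FARADAY = 96485.33212  # C mol^-1
RT = 8.314462618 * 298.15  # J mol^-1
DAVIES_A = 0.509
GC_PREFACTOR = 0.1174  # C m^-2 M^-0.5, sqrt(8*eps0*eps_r*RT*1000) at 25 C
LN10 = math.log(10.0)
AVOGADRO = 6.02214076e23
#: sites nm^-2 per umol m^-2
SITES_PER_UMOL = AVOGADRO * 1e-6 / 1e18


class SpeciationError(RuntimeError):
    """Base class for equilibrium-solver failures."""


class ConvergenceError(SpeciationError):
    """Newton iteration did not reach tolerance; carries final residuals."""

    def __init__(self, msg: str, residuals: Mapping[str, float] | None = None):
        super().__init__(msg)
        self.residuals = dict(residuals or {})


class InfeasibleSystemError(SpeciationError):
    """Surface-component totals exceed the sites available to host them."""


def davies_log_gamma(charge: float, ionic_strength: float) -> float:
    """Davies log10 activity coefficient at 25 C.

    log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I), A = 0.509.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if charge == 0 or ionic_strength == 0:
        return 0.0
    s = math.sqrt(ionic_strength)
    return -DAVIES_A * charge * charge * (s / (1.0 + s) - 0.3 * ionic_strength)


def gouy_chapman_sigma(psi_d: float, electrolyte_conc: float) -> float:
    """Diffuse-layer charge (C m^-2) for a symmetric 1:1 electrolyte at 25 C.

    sigma_d = -0.1174 sqrt(c) sinh(F psi_d / 2RT); the sign is opposite to
    the potential at the head of the diffuse layer.
    """
    return -GC_PREFACTOR * math.sqrt(electrolyte_conc) * math.sinh(
        FARADAY * psi_d / (2.0 * RT))


@dataclass(frozen=True)
class EDLParameters:
    """Compact-layer capacitances and the surface-to-volume geometry.

    c1, c2 in F m^-2 (inner / outer Stern capacitor), specific surface area
    in m^2 g^-1, solid concentration in g L^-1.
    """

    c1: float
    c2: float
    specific_surface_area: float
    solid_concentration: float

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "specific_surface_area", "solid_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"EDLParameters.{name} must be > 0")

    @property
    def area_per_litre(self) -> float:
        """m^2 of surface per litre of suspension."""
        return self.specific_surface_area * self.solid_concentration


@dataclass(frozen=True)
class EDLState:
    """Potentials (V) and charges (C m^-2) of the three planes and the
    diffuse layer of a converged system."""

    psi0: float
    psi1: float
    psi2: float
    sigma0: float
    sigma1: float
    sigma2: float
    sigma_d: float

    @property
    def charge_balance(self) -> float:
        return self.sigma0 + self.sigma1 + self.sigma2 + self.sigma_d


@dataclass
class SystemComposition:
    """Totals and imposed activities of one equilibrium problem.

    ``totals`` holds mol L^-1 for aqueous masters and mol m^-2 for surface
    components (HNOM, S0); surface-site totals follow from the database site
    densities.  ``fixed_activities`` imposes activities (e.g. H+ when pH is
    measured); a component may not appear in both.  ``ionic_strength`` is the
    nominal value used for activity corrections and the diffuse layer, or
    None to iterate it from the computed speciation.
    """

    totals: dict[str, float] = field(default_factory=dict)
    fixed_activities: dict[str, float] = field(default_factory=dict)
    ionic_strength: float | None = None

    def __post_init__(self) -> None:
        both = set(self.totals) & set(self.fixed_activities)
        if both:
            raise ValueError(f"component(s) {sorted(both)} given as both total and fixed activity")
        neg = {k: v for k, v in self.totals.items() if v < 0}
        if neg:
            raise ValueError(f"negative totals: {neg}")


@dataclass(frozen=True)
class SolverOptions:
    tol: float = 1e-11
    max_iter: int = 200
    max_step: float = 2.0  # decades per Newton step
    ionic_strength_iter: int = 30


@dataclass
class SpeciationResult:
    """Converged speciation: free component activities, species amounts
    (mol L^-1 aqueous, mol m^-2 surface), the electrostatic state and solver
    diagnostics."""

    free_activities: dict[str, float]
    species_amounts: dict[str, float]
    edl: EDLState | None
    converged: bool
    iterations: int
    residual_norm: float
    ionic_strength: float = 0.0
    _warm_start: np.ndarray | None = None

    def total_aqueous(self, component: str, db: ModelDatabase) -> float:
        """Summed dissolved mol L^-1 of a component over aqueous species."""
        return sum(sp.stoichiometry.get(component, 0.0) * self.species_amounts[sp.name]
                   for sp in db.species if sp.phase == "aqueous"
                   and sp.name in self.species_amounts)

    def total_adsorbed(self, component: str, db: ModelDatabase) -> float:
        """Summed adsorbed mol m^-2 of a component over surface species."""
        return sum(sp.stoichiometry.get(component, 0.0) * self.species_amounts[sp.name]
                   for sp in db.species if sp.phase == "surface"
                   and sp.name in self.species_amounts)


# ---------------------------------------------------------------------------
# Tableau compilation (cached per database identity)
# ---------------------------------------------------------------------------

class _Tableau:
    """Arrays compiled once per database: stoichiometric matrix, logK, dz,
    plane charges and aqueous species charges."""

    def __init__(self, db: ModelDatabase):
        self.db = db
        self.comp_names = [c.name for c in db.components]
        self.comp_kind = {c.name: c.kind for c in db.components}
        self.comp_charge = {c.name: c.charge for c in db.components}
        self.site_density = {c.name: c.site_density for c in db.components
                             if c.kind == SURFACE_SITE}
        ncomp = len(self.comp_names)
        nsp = len(db.species)
        idx = {n: j for j, n in enumerate(self.comp_names)}
        self.N = np.zeros((nsp, ncomp))
        self.logk = np.zeros(nsp)
        self.dz = np.zeros((nsp, 3))
        self.zplane = np.zeros((nsp, 3))
        self.is_surface = np.zeros(nsp, dtype=bool)
        self.z_aq = np.zeros(nsp)
        self.sp_names = [s.name for s in db.species]
        for i, s in enumerate(db.species):
            self.logk[i] = s.logk
            self.dz[i] = s.dz
            self.is_surface[i] = s.phase == "surface"
            for n, nu in s.stoichiometry.items():
                self.N[i, idx[n]] = nu
            z0, z1, z2 = db.plane_charges(s)
            self.zplane[i] = (z0, z1, z2) if self.is_surface[i] else (0, 0, 0)
            self.z_aq[i] = db.aqueous_charge(s)


_TABLEAU_CACHE: dict[int, tuple[ModelDatabase, _Tableau]] = {}


def _tableau(db: ModelDatabase) -> _Tableau:
    hit = _TABLEAU_CACHE.get(id(db))
    if hit is not None and hit[0] is db:
        return hit[1]
    t = _Tableau(db)
    if len(_TABLEAU_CACHE) > 64:
        _TABLEAU_CACHE.clear()
    _TABLEAU_CACHE[id(db)] = (db, t)
    return t


# ---------------------------------------------------------------------------
# The solver
# ---------------------------------------------------------------------------

def solve_equilibrium(db: ModelDatabase, comp: SystemComposition,
                      edlp: EDLParameters | None,
                      options: SolverOptions | None = None,
                      warm_start: SpeciationResult | None = None) -> SpeciationResult:
    """Solve one equilibrium problem.

    Components with zero totals (and the species containing them) are removed
    before solving.  Raises :class:`InfeasibleSystemError` when the HNOM+S0
    demand exceeds the singly coordinated site total, and
    :class:`ConvergenceError` (with residuals) when Newton fails.
    Deterministic: identical inputs give bit-identical results.
    """
    opts = options or SolverOptions()
    t = _tableau(db)
    area = edlp.area_per_litre if edlp is not None else 0.0

    # --- assemble totals in mol/L of suspension --------------------------
    totals_L: dict[str, float] = {}
    for name in t.comp_names:
        kind = t.comp_kind[name]
        if name in comp.fixed_activities:
            continue
        if kind == AQUEOUS_MASTER:
            totals_L[name] = comp.totals.get(name, 0.0)
        elif kind == SURFACE_SITE:
            if edlp is None:
                totals_L[name] = 0.0
            else:
                sd = t.site_density[name]  # sites nm^-2
                totals_L[name] = sd / SITES_PER_UMOL * 1e-6 * area  # mol/L
        else:  # surface component: totals given in mol m^-2
            totals_L[name] = comp.totals.get(name, 0.0) * area

    # feasibility: every HNOM and S0 consumes one singly coordinated site
    if "FeOH" in totals_L:
        demand = totals_L.get("HNOM", 0.0) + totals_L.get("S0", 0.0)
        if demand >= totals_L["FeOH"] > 0:
            raise InfeasibleSystemError(
                "site balance 'FeOH' infeasible: HNOM + S0 demand "
                f"({demand:.3e} mol/L) >= singly coordinated site total "
                f"({totals_L['FeOH']:.3e} mol/L)")

    # --- reduce the tableau ----------------------------------------------
    fixed_logact = {k: math.log10(v) for k, v in comp.fixed_activities.items()}
    active = [n for n in t.comp_names
              if n in fixed_logact or totals_L.get(n, 0.0) > 0.0]
    drop = [n for n in t.comp_names if n not in active]
    keep_sp = np.ones(len(t.sp_names), dtype=bool)
    for n in drop:
        j = t.comp_names.index(n)
        keep_sp &= t.N[:, j] == 0.0
    free = [n for n in active if n not in fixed_logact]
    jfree = [t.comp_names.index(n) for n in free]
    jfix = [t.comp_names.index(n) for n in fixed_logact]
    ufix = np.array([fixed_logact[t.comp_names[j]] for j in jfix])

    N = t.N[keep_sp]
    Nf = N[:, jfree]
    logk_eff = t.logk[keep_sp] + (N[:, jfix] @ ufix if jfix else 0.0)
    dz = t.dz[keep_sp]
    zpl = t.zplane[keep_sp]
    surf = t.is_surface[keep_sp]
    z_aq = t.z_aq[keep_sp]
    names = [n for n, k in zip(t.sp_names, keep_sp) if k]
    T = np.array([totals_L[n] for n in free])

    has_surface = bool(surf.any()) and area > 0.0
    nfree = len(free)
    nplanes = 3 if has_surface else 0

    # --- initial guess ----------------------------------------------------
    if warm_start is not None and warm_start._warm_start is not None \
            and len(warm_start._warm_start) == nfree + nplanes:
        x = warm_start._warm_start.copy()
    else:
        x = np.empty(nfree + nplanes)
        for k, n in enumerate(free):
            frac = 0.1 if t.comp_kind[n] == AQUEOUS_MASTER else 0.5
            x[k] = math.log10(max(T[k] * frac, 1e-30))
        x[nfree:] = 0.0

    nominal_I = comp.ionic_strength
    ionic = nominal_I if nominal_I is not None else 0.0

    def _solve_at_I(x: np.ndarray, ionic: float):
        lgam = np.array([0.0 if s else davies_log_gamma(z, ionic)
                         for s, z in zip(surf, z_aq)])
        c_elec = max(ionic, 1e-12)
        scale = np.maximum(T, 1e-15)
        for it in range(opts.max_iter):
            loga = logk_eff + Nf @ x[:nfree]
            if nplanes:
                loga = loga + dz @ x[nfree:]
            logc = loga - lgam
            n_sp = 10.0 ** np.clip(logc, -300, 300)

            res = np.empty(nfree + nplanes)
            res[:nfree] = (Nf.T @ n_sp - T) / scale
            J = np.empty((nfree + nplanes, nfree + nplanes))
            W = n_sp[:, None] * Nf  # d n / d u / ln10
            J[:nfree, :nfree] = LN10 * (Nf.T @ W) / scale[:, None]
            if nplanes:
                sigma = (FARADAY / area) * (zpl.T @ n_sp)  # per plane, C/m^2
                psi = -(RT / FARADAY) * LN10 * x[nfree:]
                sd = gouy_chapman_sigma(psi[2], c_elec)
                e0 = sigma[0] - edlp.c1 * (psi[0] - psi[1])
                e1 = sigma[0] + sigma[1] - edlp.c2 * (psi[1] - psi[2])
                e2 = sigma[0] + sigma[1] + sigma[2] + sd
                res[nfree:] = (e0, e1, e2)
                Dz = n_sp[:, None] * dz
                dsig_du = (FARADAY / area) * LN10 * (zpl.T @ W)   # 3 x nfree
                dsig_db = (FARADAY / area) * LN10 * (zpl.T @ Dz)  # 3 x 3
                J[:nfree, nfree:] = LN10 * (Nf.T @ Dz) / scale[:, None]
                dpsi_db = -(RT / FARADAY) * LN10
                dsd_dpsi = -GC_PREFACTOR * math.sqrt(c_elec) * math.cosh(
                    FARADAY * psi[2] / (2 * RT)) * FARADAY / (2 * RT)
                J[nfree + 0, :nfree] = dsig_du[0]
                J[nfree + 1, :nfree] = dsig_du[0] + dsig_du[1]
                J[nfree + 2, :nfree] = dsig_du.sum(axis=0)
                J[nfree + 0, nfree:] = dsig_db[0]
                J[nfree + 0, nfree + 0] -= edlp.c1 * dpsi_db
                J[nfree + 0, nfree + 1] += edlp.c1 * dpsi_db
                J[nfree + 1, nfree:] = dsig_db[0] + dsig_db[1]
                J[nfree + 1, nfree + 1] -= edlp.c2 * dpsi_db
                J[nfree + 1, nfree + 2] += edlp.c2 * dpsi_db
                J[nfree + 2, nfree:] = dsig_db.sum(axis=0)
                J[nfree + 2, nfree + 2] += dsd_dpsi * dpsi_db

            norm = float(np.max(np.abs(res)))
            if norm <= opts.tol:
                return x, n_sp, it + 1, norm, True
            try:
                dx = np.linalg.solve(J, -res)
            except np.linalg.LinAlgError:
                dx = np.linalg.lstsq(J, -res, rcond=None)[0]
            big = np.max(np.abs(dx))
            if big > opts.max_step:
                dx *= opts.max_step / big
            # backtracking on the residual norm
            lam, best = 1.0, None
            for _ in range(12):
                xt = x + lam * dx
                loga_t = logk_eff + Nf @ xt[:nfree]
                if nplanes:
                    loga_t = loga_t + dz @ xt[nfree:]
                nt = 10.0 ** np.clip(loga_t - lgam, -300, 300)
                rt = np.empty_like(res)
                rt[:nfree] = (Nf.T @ nt - T) / scale
                if nplanes:
                    sg = (FARADAY / area) * (zpl.T @ nt)
                    ps = -(RT / FARADAY) * LN10 * xt[nfree:]
                    sdt = gouy_chapman_sigma(ps[2], c_elec)
                    rt[nfree:] = (sg[0] - edlp.c1 * (ps[0] - ps[1]),
                                  sg[0] + sg[1] - edlp.c2 * (ps[1] - ps[2]),
                                  sg[0] + sg[1] + sg[2] + sdt)
                nrm_t = float(np.max(np.abs(rt)))
                if best is None or nrm_t < best[1]:
                    best = (xt, nrm_t)
                if nrm_t < norm:
                    break
                lam *= 0.5
            x = best[0]
        return x, n_sp, opts.max_iter, norm, False

    # outer ionic-strength loop (single pass in nominal mode)
    n_outer = 1 if nominal_I is not None else opts.ionic_strength_iter
    iters_total = 0
    for outer in range(n_outer):
        x, n_sp, iters, norm, ok = _solve_at_I(x, ionic)
        iters_total += iters
        if not ok:
            raise ConvergenceError(
                f"equilibrium solver did not converge (residual {norm:.3e} "
                f"after {iters_total} iterations)", {"residual_norm": norm})
        if nominal_I is not None:
            break
        I_new = 0.5 * float(np.sum(z_aq[~surf] ** 2 * n_sp[~surf]))
        if abs(I_new - ionic) <= 1e-10 * max(I_new, 1e-10):
            ionic = I_new
            break
        ionic = I_new
    else:
        raise ConvergenceError("ionic-strength iteration did not converge",
                               {"ionic_strength": ionic})

    # --- package the result ----------------------------------------------
    amounts: dict[str, float] = {}
    for nm, amt, is_s in zip(names, n_sp, surf):
        amounts[nm] = float(amt / area) if (is_s and area > 0) else float(amt)
    acts = {n: 10.0 ** x[k] for k, n in enumerate(free)}
    acts.update(comp.fixed_activities)
    edl = None
    if has_surface:
        sigma = (FARADAY / area) * (zpl.T @ n_sp)
        psi = -(RT / FARADAY) * LN10 * x[nfree:]
        edl = EDLState(psi0=float(psi[0]), psi1=float(psi[1]), psi2=float(psi[2]),
                       sigma0=float(sigma[0]), sigma1=float(sigma[1]),
                       sigma2=float(sigma[2]),
                       sigma_d=float(gouy_chapman_sigma(psi[2], max(ionic, 1e-12))))
    return SpeciationResult(
        free_activities=acts, species_amounts=amounts, edl=edl, converged=True,
        iterations=iters_total, residual_norm=norm, ionic_strength=ionic,
        _warm_start=x.copy())
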