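"""Equilibrium solver: activity model, diffuse layer, balances, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import snomcd as sc
from snomcd.model_db import Component, ModelDatabase, Species
from snomcd.speciation import FARADAY, RT, SITES_PER_UMOL


class TestDavies:
    @pytest.mark.parametrize("z,i,expected", [
        (1, 0.0, 0.0),                     # infinite dilution
        (0, 0.5, 0.0),                     # neutral species
        (1, 0.1, -0.107018814),            # direct evaluation of the formula
        (2, 0.1, 4 * -0.107018814),        # z^2 scaling
    ])
    def test_values(self, z, i, expected):
        assert sc.davies_log_gamma(z, i) == pytest.approx(expected, abs=1e-8)

    def test_gamma_at_tenth_molar(self):
        assert 10 ** sc.davies_log_gamma(1, 0.1) == pytest.approx(0.781, abs=2e-3)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            sc.davies_log_gamma(1, -0.1)


class TestGouyChapman:
    def test_zero_potential(self):
        assert sc.gouy_chapman_sigma(0.0, 0.3) == 0.0

    @given(psi=st.floats(-0.3, 0.3), c=st.floats(1e-4, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_odd_function_opposing_sign(self, psi, c):
        s = sc.gouy_chapman_sigma(psi, c)
        assert sc.gouy_chapman_sigma(-psi, c) == pytest.approx(-s, rel=1e-12)
        assert s * psi <= 0

    def test_reference_value(self):
        # -0.1174 sqrt(0.1) sinh(96485 * -0.1 / (2 * 2478.97))
        expected = 0.1174 * math.sqrt(0.1) * math.sinh(96485 * 0.1 / (2 * 2478.97))
        assert sc.gouy_chapman_sigma(-0.1, 0.1) == pytest.approx(expected, rel=1e-3)
        assert sc.gouy_chapman_sigma(-0.1, 0.1) == pytest.approx(0.1273, abs=5e-4)


def _aqueous_only_db():
    return ModelDatabase(
        components=[Component("Na", "aqueous_master", 1.0),
                    Component("NO3", "aqueous_master", -1.0),
                    Component("H", "aqueous_master", 1.0)],
        species=[Species("Na+", {"Na": 1}, 0.0), Species("NO3-", {"NO3": 1}, 0.0),
                 Species("H+", {"H": 1}, 0.0), Species("OH-", {"H": -1}, -14.0)])


class TestInertSystem:
    def test_nano3_only(self):
        """Inert electrolyte at fixed pH: free equals total, bulk electroneutral."""
        db = _aqueous_only_db()
        comp = sc.SystemComposition(totals={"Na": 0.1, "NO3": 0.1},
                                    fixed_activities={"H": 1e-7},
                                    ionic_strength=0.1)
        res = sc.solve_equilibrium(db, comp, None)
        assert res.converged
        assert res.species_amounts["Na+"] == pytest.approx(0.1, rel=1e-10)
        assert res.species_amounts["NO3-"] == pytest.approx(0.1, rel=1e-10)
        assert res.edl is None
        net = sum(z * res.species_amounts[n] for n, z in
                  [("Na+", 1), ("NO3-", -1)])
        assert net == pytest.approx(0.0, abs=1e-12)

    def test_computed_ionic_strength_mode(self):
        db = _aqueous_only_db()
        comp = sc.SystemComposition(totals={"Na": 0.05, "NO3": 0.05},
                                    fixed_activities={"H": 1e-7},
                                    ionic_strength=None)
        res = sc.solve_equilibrium(db, comp, None)
        # I = 0.5 sum(c z^2); activity corrections shift concentrations above totals
        assert res.ionic_strength == pytest.approx(0.05, rel=0.1)
        assert res.ionic_strength > 0.05


class TestBareGoethite:
    def test_pzc_at_9p3(self, config, edlp):
        """Surface charge of bare goethite crosses zero at the PZC, located
        by bisection on sigma0(pH)."""
        db = sc.default_database(config, include_pmg=False, include_nom=False,
                                 include_steric=False)

        def sigma0(ph):
            comp = sc.SystemComposition(totals={"Na": 0.1, "NO3": 0.1},
                                        fixed_activities={"H": 10 ** -ph},
                                        ionic_strength=0.1)
            return sc.solve_equilibrium(db, comp, edlp).edl.sigma0

        lo, hi = 8.0, 10.5
        assert sigma0(lo) > 0 > sigma0(hi)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if sigma0(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(9.3, abs=1e-4)

    def test_edl_state_consistency(self, config, edlp):
        db = sc.default_database(config, include_pmg=False, include_nom=False,
                                 include_steric=False)
        comp = sc.SystemComposition(totals={"Na": 0.1, "NO3": 0.1},
                                    fixed_activities={"H": 1e-5},
                                    ionic_strength=0.1)
        e = sc.solve_equilibrium(db, comp, edlp).edl
        assert e.sigma0 == pytest.approx(edlp.c1 * (e.psi0 - e.psi1), abs=1e-10)
        assert e.sigma0 + e.sigma1 == pytest.approx(edlp.c2 * (e.psi1 - e.psi2), abs=1e-10)
        assert e.sigma_d == pytest.approx(sc.gouy_chapman_sigma(e.psi2, 0.1), abs=1e-12)
        assert abs(e.charge_balance) < 1e-10


def _langmuir_db(logk=5.0):
    return ModelDatabase(
        components=[Component("S", "surface_site", 0.0, site_density=1.0),
                    Component("L", "aqueous_master", 0.0)],
        species=[Species("S", {"S": 1}, 0.0, phase="surface"),
                 Species("L", {"L": 1}, 0.0),
                 Species("SL", {"S": 1, "L": 1}, logk, phase="surface")])


class TestLangmuirOracle:
    @pytest.mark.parametrize("ltot", [1e-6, 1e-4, 1e-2])
    def test_matches_closed_form(self, ltot):
        """Neutral single-site binding with electrostatics off equals the
        algebraic Langmuir solution."""
        db = _langmuir_db()
        edlp = sc.EDLParameters(1e6, 1e6, 10.0, 1.0)
        comp = sc.SystemComposition(totals={"L": ltot}, ionic_strength=0.01)
        res = sc.solve_equilibrium(db, comp, edlp)
        K = 10.0 ** 5
        stot = 1.0 / SITES_PER_UMOL * 1e-6 * 10.0  # mol/L of sites
        a, b, c = K, -(K * ltot + K * stot + 1.0), K * ltot * stot
        sl_exact = (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)
        sl_model = res.species_amounts["SL"] * 10.0  # mol/m2 -> mol/L
        assert sl_model == pytest.approx(sl_exact, rel=1e-8)


def _fixed_point_oracle(totals, species, max_iter=200000):
    """Independent non-electrostatic speciation by successive substitution.

    ``species`` is a list of (stoich dict, K); returns species concentrations.
    """
    free = {k: v * 0.1 + 1e-30 for k, v in totals.items()}
    for _ in range(max_iter):
        conc = [k * np.prod([free[c] ** nu for c, nu in sto.items()])
                for sto, k in species]
        calc = {c: sum(sto.get(c, 0) * x for (sto, _), x in zip(species, conc))
                for c in totals}
        done = all(abs(calc[c] - totals[c]) <= 1e-13 * totals[c] for c in totals)
        if done:
            return {i: x for i, x in enumerate(conc)}
        for c in totals:
            free[c] *= (totals[c] / max(calc[c], 1e-300)) ** 0.5
    raise RuntimeError("oracle did not converge")


class TestElectrostaticsOffLimit:
    def test_two_component_system_matches_fixed_point_oracle(self):
        """All dz = 0 and huge capacitances: the Newton solver must agree
        with an independent fixed-point speciation solver."""
        db = ModelDatabase(
            components=[Component("S", "surface_site", 0.0, site_density=2.0),
                        Component("L", "aqueous_master", 0.0),
                        Component("M", "aqueous_master", 0.0)],
            species=[Species("S", {"S": 1}, 0.0, phase="surface"),
                     Species("L", {"L": 1}, 0.0),
                     Species("M", {"M": 1}, 0.0),
                     Species("SL", {"S": 1, "L": 1}, 4.0, phase="surface"),
                     Species("SM", {"S": 1, "M": 1}, 5.0, phase="surface"),
                     Species("SL2", {"S": 1, "L": 2}, 7.5, phase="surface")])
        edlp = sc.EDLParameters(1e7, 1e7, 5.0, 2.0)
        stot = 2.0 / SITES_PER_UMOL * 1e-6 * 10.0
        totals = {"S": stot, "L": 3e-4, "M": 1e-4}
        res = sc.solve_equilibrium(
            db, sc.SystemComposition(totals={"L": 3e-4, "M": 1e-4},
                                     ionic_strength=0.0), edlp)
        oracle = _fixed_point_oracle(
            totals,
            [({"S": 1}, 1.0), ({"L": 1}, 1.0), ({"M": 1}, 1.0),
             ({"S": 1, "L": 1}, 10 ** 4.0), ({"S": 1, "M": 1}, 10 ** 5.0),
             ({"S": 1, "L": 2}, 10 ** 7.5)])
        names = ["S", "L", "M", "SL", "SM", "SL2"]
        area = 10.0
        for i, n in enumerate(names):
            model = res.species_amounts[n]
            if db.get_species(n).phase == "surface":
                model *= area
            assert model == pytest.approx(oracle[i], rel=1e-6), n


class TestConservationAndDeterminism:
    def test_mass_and_charge_balance_full_system(self, full_db, edlp):
        comp = sc.SystemComposition(
            totals={"Na": 0.1, "NO3": 0.1, "PMG": 5e-4,
                    "HNOM": 1.2e-6, "S0": 1.5e-6},
            fixed_activities={"H": 10 ** -5.5}, ionic_strength=0.1)
        res = sc.solve_equilibrium(full_db, comp, edlp)
        area = edlp.area_per_litre
        for name, tot in comp.totals.items():
            got = res.total_aqueous(name, full_db) \
                + res.total_adsorbed(name, full_db) * area
            want = tot if name not in ("HNOM", "S0") else tot * area
            assert got == pytest.approx(want, rel=1e-9), name
        assert abs(res.edl.charge_balance) < 1e-10
        assert all(v >= 0 for v in res.species_amounts.values())

    def test_bit_identical_reruns(self, full_db, edlp):
        comp = sc.SystemComposition(
            totals={"Na": 0.1, "NO3": 0.1, "PMG": 2e-4, "HNOM": 1e-6},
            fixed_activities={"H": 1e-6}, ionic_strength=0.1)
        r1 = sc.solve_equilibrium(full_db, comp, edlp)
        r2 = sc.solve_equilibrium(full_db, comp, edlp)
        assert r1.species_amounts == r2.species_amounts
        assert r1.edl == r2.edl

    def test_infeasible_surface_totals(self, full_db, edlp):
        # singly coordinated sites: 3.45 nm^-2 = 5.73 umol/m2
        comp = sc.SystemComposition(
            totals={"Na": 0.1, "NO3": 0.1, "HNOM": 4e-6, "S0": 3e-6},
            fixed_activities={"H": 1e-6}, ionic_strength=0.1)
        with pytest.raises(sc.InfeasibleSystemError, match="FeOH"):
            sc.solve_equilibrium(full_db, comp, edlp)

    def test_steric_augmentation_does_not_alter_primary_charging(self, config, edlp):
        """Blocked sites keep full proton/electrolyte chemistry: with S0
        present but PMG absent, sigma0 is unchanged vs the unaugmented model."""
        db_aug = sc.default_database(config, include_pmg=False)
        db_base = sc.default_database(config, include_pmg=False, include_steric=False)
        for ph in (4.0, 6.0, 8.0, 9.3):
            t_aug = {"Na": 0.1, "NO3": 0.1, "HNOM": 1.77e-6, "S0": 2.2e-6}
            t_base = {"Na": 0.1, "NO3": 0.1, "HNOM": 1.77e-6}
            r_aug = sc.solve_equilibrium(db_aug, sc.SystemComposition(
                totals=t_aug, fixed_activities={"H": 10 ** -ph},
                ionic_strength=0.1), edlp)
            r_base = sc.solve_equilibrium(db_base, sc.SystemComposition(
                totals=t_base, fixed_activities={"H": 10 ** -ph},
                ionic_strength=0.1), edlp)
            assert abs(r_aug.edl.sigma0 - r_base.edl.sigma0) < 1e-10
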