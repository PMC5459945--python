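"""Driving force, efficiency and protein-cost checks against analytic
values and a dense grid-search oracle."""

import math

import numpy as np
import pytest

from oracles import grid_min_cost

from orthodesign.cost import (
    DEFAULT_CONC_BOUNDS,
    EnzymeKinetics,
    InfeasibleDirectionError,
    InfiniteCostError,
    R_GAS,
    ThermodynamicInfeasibilityError,
    ThermoState,
    driving_force,
    efficiencies,
    max_min_driving_force,
    minimize_pathway_cost,
    reaction_cost,
)
from orthodesign.model import Reaction

RT = R_GAS * 298.15


def state(dg0, **log_conc):
    return ThermoState(reaction_dg0=dg0, log_conc=log_conc)


class TestDrivingForce:
    def test_standard_conditions(self):
        st = state({"r": 0.0}, A=0.0, B=0.0)
        assert driving_force(st, Reaction("r", {"A": -1, "B": 1})) == 0.0

    def test_tenfold_gradient(self):
        st = state({"r": 0.0}, A=math.log(10.0), B=0.0)
        dg = driving_force(st, Reaction("r", {"A": -1, "B": 1}))
        assert dg == pytest.approx(-RT * math.log(10.0))
        assert dg == pytest.approx(-5.71, abs=0.01)

    def test_stoichiometry_scales_concentration_term(self):
        st = state({"r": 0.0, "r2": 0.0}, A=1.0, B=0.0)
        single = driving_force(st, Reaction("r", {"A": -1, "B": 1}))
        double = driving_force(st, Reaction("r2", {"A": -2, "B": 2}))
        assert double == pytest.approx(2 * single)

    def test_missing_concentration_named(self):
        st = state({"r": 0.0}, A=0.0)
        with pytest.raises(Exception, match="B"):
            driving_force(st, Reaction("r", {"A": -1, "B": 1}))


class TestEfficiencies:
    def test_eta_therm_at_tenfold_driving_force(self):
        st = state({"r": 0.0}, A=math.log(10.0), B=0.0)
        kin = EnzymeKinetics("r", 1.0, {}, 1.0)
        eta_t, _ = efficiencies(st, kin, Reaction("r", {"A": -1, "B": 1}))
        assert eta_t == pytest.approx(0.9)

    def test_eta_sat_half_at_km(self):
        st = state({"r": -50.0}, A=math.log(1e-4), B=0.0)
        kin = EnzymeKinetics("r", 1.0, {"A": 1e-4}, 1.0)
        _, eta_s = efficiencies(st, kin, Reaction("r", {"A": -1, "B": 1}))
        assert eta_s == pytest.approx(0.5)

    def test_eta_therm_limit_one(self):
        st = state({"r": -1e4}, A=0.0, B=0.0)
        eta_t, _ = efficiencies(st, EnzymeKinetics("r", 1, {}, 1), Reaction("r", {"A": -1, "B": 1}))
        assert eta_t == pytest.approx(1.0)

    def test_uphill_direction_rejected(self):
        st = state({"r": 10.0}, A=0.0, B=0.0)
        with pytest.raises(InfeasibleDirectionError):
            efficiencies(st, EnzymeKinetics("r", 1, {}, 1), Reaction("r", {"A": -1, "B": 1}))

    def test_multiplicative_saturation_over_substrates(self):
        st = state({"r": -50.0}, A=math.log(1e-4), B=math.log(1e-4), C=0.0)
        kin = EnzymeKinetics("r", 1.0, {"A": 1e-4, "B": 1e-4}, 1.0)
        _, eta_s = efficiencies(st, kin, Reaction("r", {"A": -1, "B": -1, "C": 1}))
        assert eta_s == pytest.approx(0.25)


class TestReactionCost:
    def test_direct_formula(self):
        kin = EnzymeKinetics("r", 10.0, {}, 100.0)
        assert reaction_cost(1.0, kin, 0.9, 0.5) == pytest.approx(100 / (10 * 0.5 * 0.9))
        assert reaction_cost(1.0, kin, 0.9, 0.5) == pytest.approx(22.22, abs=0.01)

    def test_ideal_enzyme_floor(self):
        kin = EnzymeKinetics("r", 10.0, {}, 100.0)
        assert reaction_cost(1.0, kin, 1.0, 1.0) == pytest.approx(10.0)

    def test_halving_kcat_doubles_cost(self):
        slow = EnzymeKinetics("r", 5.0, {}, 100.0)
        fast = EnzymeKinetics("r", 10.0, {}, 100.0)
        assert reaction_cost(1.0, slow, 0.8, 0.5) == pytest.approx(
            2 * reaction_cost(1.0, fast, 0.8, 0.5))

    def test_flux_weighting(self):
        kin = EnzymeKinetics("r", 10.0, {}, 100.0)
        assert reaction_cost(2.0, kin, 1.0, 1.0) == pytest.approx(20.0)

    def test_zero_efficiency_is_an_error_not_inf(self):
        kin = EnzymeKinetics("r", 10.0, {}, 100.0)
        with pytest.raises(InfiniteCostError):
            reaction_cost(1.0, kin, 0.0, 0.5)


def chain_pathway():
    """S -> M -> P with one shared intermediate."""
    rA = Reaction("rA", {"S": -1, "M": 1})
    rB = Reaction("rB", {"M": -1, "P": 1})
    kinetics = {
        "rA": EnzymeKinetics("rA", 50.0, {"S": 1e-4}, 40000.0),
        "rB": EnzymeKinetics("rB", 30.0, {"M": 1e-4}, 60000.0),
    }
    thermo = ThermoState(reaction_dg0={"rA": -10.0, "rB": -10.0})
    return [(rA, 1.0), (rB, 1.0)], kinetics, thermo


class TestPathwayOptimization:
    def test_single_reaction_pushes_to_bounds(self):
        r = Reaction("r", {"S": -1, "P": 1})
        kin = {"r": EnzymeKinetics("r", 10.0, {"S": 1e-4}, 1000.0)}
        thermo = ThermoState(reaction_dg0={"r": -30.0})
        res = minimize_pathway_cost([(r, 1.0)], kin, thermo)
        # optimum: substrate at its upper bound (max saturation), product at
        # its lower bound (max driving force)
        assert res.optimal_log_conc["S"] == pytest.approx(math.log(DEFAULT_CONC_BOUNDS[1]), abs=1e-3)
        assert res.optimal_log_conc["P"] == pytest.approx(math.log(DEFAULT_CONC_BOUNDS[0]), abs=1e-3)
        eta_s_max = (1e-2 / 1e-4) / (1 + 1e-2 / 1e-4)
        assert res.total_cost == pytest.approx(1000.0 / (10.0 * eta_s_max), rel=1e-3)

    @pytest.mark.parametrize("points", [50])
    def test_two_step_chain_beats_grid_oracle(self, points):
        pathway, kinetics, thermo = chain_pathway()
        res = minimize_pathway_cost(pathway, kinetics, thermo)
        grid = grid_min_cost(pathway, kinetics, thermo, points_per_dim=points)
        assert res.total_cost <= grid * 1.01

    def test_three_step_chain_beats_grid_oracle(self):
        rA = Reaction("rA", {"S": -1, "M1": 1})
        rB = Reaction("rB", {"M1": -1, "M2": 1})
        rC = Reaction("rC", {"M2": -1, "P": 1})
        kinetics = {
            "rA": EnzymeKinetics("rA", 20.0, {"S": 5e-4}, 50000.0),
            "rB": EnzymeKinetics("rB", 8.0, {"M1": 2e-4}, 30000.0),
            "rC": EnzymeKinetics("rC", 60.0, {"M2": 1e-3}, 80000.0),
        }
        thermo = ThermoState(reaction_dg0={"rA": -5.0, "rB": -12.0, "rC": -8.0})
        pathway = [(rA, 1.0), (rB, 1.0), (rC, 1.0)]
        res = minimize_pathway_cost(pathway, kinetics, thermo)
        grid = grid_min_cost(pathway, kinetics, thermo, points_per_dim=30)
        assert res.total_cost <= grid * 1.01

    def test_tightening_intermediate_bound_weakly_increases_cost(self):
        pathway, kinetics, thermo = chain_pathway()
        loose = minimize_pathway_cost(pathway, kinetics, thermo).total_cost
        tight_thermo = ThermoState(
            reaction_dg0=thermo.reaction_dg0,
            conc_bounds={"M": (1e-6, 1e-5)},
        )
        tight = minimize_pathway_cost(pathway, kinetics, tight_thermo).total_cost
        assert tight >= loose - 1e-9

    def test_infeasible_pathway_lists_bottlenecks(self):
        r = Reaction("r", {"S": -1, "P": 1})
        kin = {"r": EnzymeKinetics("r", 10.0, {"S": 1e-4}, 1000.0)}
        thermo = ThermoState(reaction_dg0={"r": +50.0})
        with pytest.raises(ThermodynamicInfeasibilityError) as exc:
            minimize_pathway_cost([(r, 1.0)], kin, thermo)
        assert "r" in exc.value.bottlenecks

    def test_thermo_contribution_vanishes_for_strong_driving_force(self):
        r = Reaction("r", {"S": -1, "P": 1})
        kin = {"r": EnzymeKinetics("r", 10.0, {"S": 1e-4}, 1000.0)}
        res = minimize_pathway_cost([(r, 1.0)], kin, ThermoState(reaction_dg0={"r": -100.0}))
        assert 0.0 <= res.thermo_contribution < 1e-6

    def test_thermo_contribution_in_range(self):
        pathway, kinetics, thermo = chain_pathway()
        res = minimize_pathway_cost(pathway, kinetics, thermo)
        assert 0.0 <= res.thermo_contribution < 100.0

    def test_cost_scales_linearly_with_flux_basis(self):
        pathway, kinetics, thermo = chain_pathway()
        base = minimize_pathway_cost(pathway, kinetics, thermo)
        doubled = minimize_pathway_cost(
            [(r, 2 * f) for r, f in pathway], kinetics, thermo)
        assert doubled.total_cost == pytest.approx(2 * base.total_cost, rel=1e-6)


class TestMDF:
    def test_feasible_chain_positive_mdf(self):
        pathway, _, thermo = chain_pathway()
        mdf, logc = max_min_driving_force([r for r, _ in pathway], thermo)
        assert mdf > 0
        lo, hi = math.log(DEFAULT_CONC_BOUNDS[0]), math.log(DEFAULT_CONC_BOUNDS[1])
        assert all(lo - 1e-9 <= v <= hi + 1e-9 for v in logc.values())

    def test_uphill_chain_flagged(self):
        r = Reaction("r", {"S": -1, "P": 1})
        thermo = ThermoState(reaction_dg0={"r": +50.0})
        # with a 1 uM..10 mM window the concentration term spans at most
        # +-RT ln(1e4) ~ 22.8 kJ/mol, which cannot overcome +50
        with pytest.raises(ThermodynamicInfeasibilityError):
            mdf, _ = max_min_driving_force([r], thermo)
            if mdf <= 0:
                raise ThermodynamicInfeasibilityError(["r"])
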