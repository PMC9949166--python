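import math

import numpy as np
import pytest

from prebioscreen import fba_engine as fe
from prebioscreen.model_core import BIG, Medium, MetabolicModel, Metabolite, Reaction, apply_medium
from prebioscreen.synthetic_data import SpeciesSpec, generate_species_model

from .conftest import random_species_spec
from .oracles import cobra_fba_objective


def constrained(spec: SpeciesSpec, medium: dict[str, float]) -> MetabolicModel:
    return apply_medium(generate_species_model(spec), Medium(medium))


class TestSolveFba:
    def test_single_bottleneck(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0}), {"A": 10.0})
        sol = fe.solve_fba(m)
        assert sol.ok and sol.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_starvation(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0}), {})
        sol = fe.solve_fba(m)
        assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_two_route_optimum_matches_independent_solver(self):
        # EX_A lb=-10 at yield 1 plus EX_B lb=-5 at yield 2 -> mu = 20
        m = constrained(SpeciesSpec("s", {"A": 1.0, "B": 2.0}), {"A": 10.0, "B": 5.0})
        sol = fe.solve_fba(m)
        assert sol.objective_value == pytest.approx(20.0, abs=1e-6)
        status, obj = cobra_fba_objective(m)
        assert status == "optimal" and obj == pytest.approx(sol.objective_value, abs=1e-6)

    def test_steady_state_and_bounds_satisfied(self):
        m = constrained(SpeciesSpec("s", {"A": 1.3, "B": 0.4}), {"A": 3.0, "B": 7.0})
        sol = fe.solve_fba(m)
        for rid, r in m.reactions.items():
            assert r.lower_bound - 1e-6 <= sol.fluxes[rid] <= r.upper_bound + 1e-6
        balance: dict[str, float] = {}
        for rid, r in m.reactions.items():
            for mid, c in r.stoichiometry.items():
                balance[mid] = balance.get(mid, 0.0) + c * sol.fluxes[rid]
        assert all(abs(v) < 1e-6 for v in balance.values())

    def test_backends_agree(self):
        rng = np.random.default_rng(11)
        for i in range(20):
            spec = random_species_spec(rng, i)
            med = {c: float(rng.uniform(0, 10)) for c in spec.uptake_compounds}
            m = constrained(spec, med)
            a = fe.solve_fba(m, backend="scipy")
            b = fe.solve_fba(m, backend="glpk")
            assert a.status == b.status == "optimal"
            assert a.objective_value == pytest.approx(b.objective_value, abs=1e-6)

    def test_monotone_in_exchange_relaxation(self):
        rng = np.random.default_rng(5)
        for i in range(15):
            spec = random_species_spec(rng, i)
            med = {c: float(rng.uniform(0, 5)) for c in spec.uptake_compounds}
            m = constrained(spec, med)
            base = fe.solve_fba(m).objective_value
            ex_ids = list(m.exchange_reactions)
            rid = ex_ids[int(rng.integers(len(ex_ids)))]
            m.reactions[rid].lower_bound -= float(rng.uniform(0, 5))
            relaxed = fe.solve_fba(m).objective_value
            assert relaxed >= base - 1e-6


class TestPfba:
    def test_zero_penalty_equals_plain_fba(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0, "B": 2.0}), {"A": 10.0, "B": 5.0})
        assert fe.solve_fba_pfba(m, 0.0).objective_value == pytest.approx(
            fe.solve_fba(m).objective_value
        )

    def test_futile_cycle_suppressed(self):
        m = generate_species_model(SpeciesSpec("s", {"A": 1.0}))
        # reversible loop A_c <-> B_c through two parallel reactions: can carry
        # arbitrary circulating flux without affecting growth
        m.metabolites["B_loop"] = Metabolite("B_loop", compartment="c")
        m.reactions["L1"] = Reaction("L1", {"A_c": -1.0, "B_loop": 1.0}, -BIG, BIG)
        m.reactions["L2"] = Reaction("L2", {"B_loop": -1.0, "A_c": 1.0}, -BIG, BIG)
        m = apply_medium(m, Medium({"A": 10.0}))
        sol = fe.solve_fba_pfba(m, 1e-6)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-4)
        assert abs(sol.fluxes["L1"]) < 1e-6 and abs(sol.fluxes["L2"]) < 1e-6

    @pytest.mark.parametrize("penalty", [1e-2, 1e-4, 1e-6])
    def test_objective_converges_to_fba(self, penalty):
        m = constrained(SpeciesSpec("s", {"A": 0.8, "B": 1.7}), {"A": 4.0, "B": 6.0})
        plain = fe.solve_fba(m)
        pen = fe.solve_fba_pfba(m, penalty)
        total_flux = sum(abs(v) for v in plain.fluxes.values())
        assert plain.objective_value - pen.objective_value <= penalty * total_flux + 1e-9

    def test_backends_agree_with_penalty(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0, "B": 2.0}), {"A": 10.0, "B": 5.0})
        a = fe.solve_fba_pfba(m, 1e-6, backend="scipy")
        b = fe.solve_fba_pfba(m, 1e-6, backend="glpk")
        assert a.objective_value == pytest.approx(b.objective_value, abs=1e-6)


class TestUptakeTest:
    def test_pathway_absorbs_full_bound(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0}), {"A": 10.0})
        assert fe.min_exchange_flux(m, "EX_A") == pytest.approx(-10.0, abs=1e-6)
        assert fe.can_take_up(m, "EX_A")

    def test_dead_end_forced_to_zero(self):
        m = constrained(
            SpeciesSpec("s", {"A": 1.0}, dead_end_compounds={"D"}), {"A": 5.0, "D": 5.0}
        )
        assert fe.min_exchange_flux(m, "EX_D") == pytest.approx(0.0, abs=1e-9)
        assert not fe.can_take_up(m, "EX_D")

    def test_couptake_of_absent_partner_blocks_uptake(self):
        # consuming C requires one unit of D per unit C; D unavailable -> 0
        mets = {
            "C": Metabolite("C", compartment="e"),
            "D": Metabolite("D", compartment="e"),
            "X": Metabolite("X", compartment="c"),
        }
        rxns = {
            "EX_C": Reaction("EX_C", {"C": -1.0}, -10.0, BIG, is_exchange=True),
            "EX_D": Reaction("EX_D", {"D": -1.0}, 0.0, BIG, is_exchange=True),
            "CONV": Reaction("CONV", {"C": -1.0, "D": -1.0, "X": 1.0}, 0.0, BIG),
            "GROW": Reaction("GROW", {"X": -1.0}, 0.0, BIG, objective_coefficient=1.0),
        }
        m = MetabolicModel("co", mets, rxns, "GROW")
        m.validate()
        assert fe.min_exchange_flux(m, "EX_C") == pytest.approx(0.0, abs=1e-9)
        # open D and C becomes consumable
        m.reactions["EX_D"].lower_bound = -10.0
        assert fe.min_exchange_flux(m, "EX_C") == pytest.approx(-10.0, abs=1e-6)

    def test_noise_below_tolerance_suppressed(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0}), {"A": 1e-9})
        assert not fe.can_take_up(m, "EX_A", tol=1e-6)

    def test_non_exchange_id_rejected(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0}), {"A": 1.0})
        with pytest.raises(ValueError):
            fe.min_exchange_flux(m, "TR_A")

    def test_invariant_to_objective_scaling(self):
        m = constrained(SpeciesSpec("s", {"A": 1.0, "B": 0.0}), {"A": 2.0, "B": 2.0})
        before = {rid: fe.can_take_up(m, rid) for rid in m.exchange_reactions}
        m.reactions[m.biomass_reaction_id].objective_coefficient = 250.0
        after = {rid: fe.can_take_up(m, rid) for rid in m.exchange_reactions}
        assert before == after


def test_infeasible_status_reported():
    mets = {"A": Metabolite("A", compartment="e"), "X": Metabolite("X", compartment="c")}
    rxns = {
        "EX_A": Reaction("EX_A", {"A": -1.0}, 0.0, BIG, is_exchange=True),
        # forced consumption of X with nothing producing it
        "SINK": Reaction("SINK", {"X": -1.0}, 1.0, BIG, objective_coefficient=1.0),
    }
    m = MetabolicModel("bad", mets, rxns, "SINK")
    sol = fe.solve_fba(m)
    assert sol.status == "infeasible"
    assert math.isnan(sol.objective_value)
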