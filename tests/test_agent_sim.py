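import numpy as np
import pandas as pd
import pytest

from prebioscreen import agent_sim as ab
from prebioscreen.model_core import Medium
from prebioscreen.synthetic_data import SpeciesSpec, generate_species_model


@pytest.fixture()
def one_eater():
    return generate_species_model(SpeciesSpec("sp", {"A": 1.0}))


@pytest.fixture()
def two_identical():
    return [
        generate_species_model(SpeciesSpec("sp1", {"A": 1.0})),
        generate_species_model(SpeciesSpec("sp2", {"A": 1.0})),
    ]


SMALL = ab.ArenaConfig(grid_shape=(6, 6), n_individuals_per_species=5)


class TestInit:
    def test_individual_counts(self, two_identical):
        arena = ab.init_arena(two_identical, Medium({"A": 10.0}), seed=1, config=SMALL)
        counts = {}
        for ind in arena.individuals:
            counts[ind.species_id] = counts.get(ind.species_id, 0) + 1
        assert counts == {"sp1": 5, "sp2": 5}

    def test_same_seed_identical_arena(self, two_identical):
        a = ab.init_arena(two_identical, Medium({"A": 10.0}), seed=3, config=SMALL)
        b = ab.init_arena(two_identical, Medium({"A": 10.0}), seed=3, config=SMALL)
        assert [(i.species_id, i.position, i.biomass) for i in a.individuals] == [
            (i.species_id, i.position, i.biomass) for i in b.individuals
        ]
        for cid in a.substrate:
            assert np.array_equal(a.substrate[cid], b.substrate[cid])

    def test_dilution_and_cell_volume_arithmetic(self, one_eater):
        # 10 mM diluted 1000-fold in a 1 uL cell -> 0.01 mM * 1e-6 L = 1e-8 mmol
        arena = ab.init_arena([one_eater], Medium({"A": 10.0}), seed=0, config=SMALL)
        assert arena.substrate["A"][0, 0] == pytest.approx(1e-8)


class TestStep:
    def test_starvation_keeps_biomass_constant(self, one_eater):
        arena = ab.init_arena([one_eater], Medium({}), seed=0, config=SMALL)
        b0 = arena.total_biomass()["sp"]
        for _ in range(4):
            ab.step(arena)
        assert arena.total_biomass()["sp"] == pytest.approx(b0)

    def test_single_agent_closed_form_growth(self, one_eater):
        # uptake bound u = local/(biomass*dt); biomass' = biomass*(1+y*u*dt)
        # = biomass + y*local, i.e. the full local amount converted at yield y
        cfg = ab.ArenaConfig(grid_shape=(1, 1), n_individuals_per_species=1,
                             diffusion_rate=0.0, initial_biomass=5e-7)
        arena = ab.init_arena([one_eater], Medium({"A": 10.0}), seed=0, config=cfg)
        local = arena.substrate["A"][0, 0]
        b0 = arena.individuals[0].biomass
        ab.step(arena)
        total = sum(i.biomass for i in arena.individuals)
        assert total == pytest.approx(b0 + 1.0 * local, rel=1e-9)
        assert arena.substrate["A"][0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_substrate_never_negative_and_consumption_bounded(self, two_identical):
        arena = ab.init_arena(two_identical, Medium({"A": 10.0}), seed=5, config=SMALL)
        supplied = arena.substrate["A"].sum()
        for _ in range(8):
            ab.step(arena)
            assert arena.substrate["A"].min() >= -1e-9
        consumed = supplied - arena.substrate["A"].sum()
        assert consumed <= supplied + 1e-12

    def test_secretion_enters_local_cell(self):
        model = generate_species_model(
            SpeciesSpec("sec", {"A": 1.0}, secretion_products={"W": 0.5})
        )
        cfg = ab.ArenaConfig(grid_shape=(1, 1), n_individuals_per_species=1,
                             diffusion_rate=0.0)
        arena = ab.init_arena([model], Medium({"A": 10.0}), seed=0, config=cfg)
        consumed = arena.substrate["A"][0, 0]
        ab.step(arena)
        assert arena.substrate["W"][0, 0] == pytest.approx(0.5 * consumed, rel=1e-6)

    def test_monotone_growth_with_ample_substrate(self, one_eater):
        cfg = ab.ArenaConfig(grid_shape=(4, 4), n_individuals_per_species=3,
                             dilution=1.0)  # undiluted -> ample
        arena = ab.init_arena([one_eater], Medium({"A": 10.0}), seed=2, config=cfg)
        prev = arena.total_biomass()["sp"]
        for _ in range(6):
            ab.step(arena)
            cur = arena.total_biomass()["sp"]
            assert cur >= prev - 1e-15
            prev = cur


class TestDiffusion:
    def test_conserves_total_and_smooths(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(0, 1, size=(7, 9))
        total = grid.sum()
        peak = grid.max()
        ab._diffuse(grid, 0.5)
        assert grid.sum() == pytest.approx(total, abs=1e-9)
        assert grid.min() >= 0
        assert grid.max() <= peak + 1e-12

    @pytest.mark.parametrize("rate", [0.0, 0.2, 1.0])
    def test_nonnegative_at_any_rate(self, rate):
        grid = np.zeros((5, 5))
        grid[2, 2] = 1.0
        for _ in range(10):
            ab._diffuse(grid, rate)
            assert grid.min() >= -1e-15


class TestReplicates:
    def test_zero_dose_relative_changes_are_zero(self, two_identical):
        res = ab.run_supplement_replicates(
            two_identical, Medium({"A": 10.0}), "A", dose_mM=0.0,
            n_steps=3, n_replicates=3, seed=4, config=SMALL,
        )
        assert (res.relative_change["relative_change"] == 0.0).all()

    def test_same_master_seed_bit_identical(self, two_identical):
        kw = dict(dose_mM=0.01, n_steps=3, n_replicates=3, seed=11, config=SMALL)
        a = ab.run_supplement_replicates(two_identical, Medium({"A": 10.0}), "A", **kw)
        b = ab.run_supplement_replicates(two_identical, Medium({"A": 10.0}), "A", **kw)
        pd.testing.assert_frame_equal(a.trajectory, b.trajectory)
        pd.testing.assert_frame_equal(a.relative_change, b.relative_change)

    def test_timesteps_cover_initial_plus_all_iterations(self, two_identical):
        res = ab.run_supplement_replicates(
            two_identical, Medium({"A": 10.0}), None, n_steps=12, n_replicates=2,
            seed=0, config=SMALL,
        )
        assert sorted(res.trajectory["timestep"].unique()) == list(range(1, 14))

    def test_symmetric_species_show_no_systematic_bias(self, two_identical):
        res = ab.run_supplement_replicates(
            two_identical, Medium({"A": 10.0}), None, n_steps=6, n_replicates=10,
            seed=8, config=SMALL,
        )
        fb = res.final_biomass().groupby("species_id")["total_biomass"].median()
        diff = abs(fb["sp1"] - fb["sp2"]) / fb.mean()
        assert diff < 0.25  # only sampling noise separates identical species

    def test_target_favoring_compound_boosts_target_more(self):
        target = generate_species_model(SpeciesSpec("T", {"A": 1.0, "S": 1.5}))
        other = generate_species_model(SpeciesSpec("O", {"A": 1.0, "S": 1.0}))
        med = Medium({"A": 10.0, "S": 10.0})
        ctrl = ab.run_supplement_replicates(
            [target, other], med, None, n_steps=6, n_replicates=8, seed=1, config=SMALL
        )
        res = ab.run_supplement_replicates(
            [target, other], med, "S", 0.01, n_steps=6, n_replicates=8, seed=1,
            config=SMALL, control=ctrl,
        )
        med_change = res.relative_change.groupby("species_id")["relative_change"].median()
        assert med_change["T"] > med_change["O"]
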