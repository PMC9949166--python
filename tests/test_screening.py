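import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prebioscreen import screening as sc
from prebioscreen.agent_sim import AbmRunResult
from prebioscreen.model_core import BiologTable, CompoundAnnotation, Medium
from prebioscreen.synthetic_data import SpeciesSpec, generate_species_model

from .oracles import bh_stepup, fisher_p_hypergeom, ranksum_p_enumeration


class TestWilcoxon:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2], [3, 4], 1 / 3),
            ([1, 2, 3], [4, 5, 6], 0.1),
        ],
    )
    def test_exact_small_sample_values(self, x, y, expected):
        assert sc.wilcoxon_rank_sum(x, y) == pytest.approx(expected, abs=1e-12)

    def test_identical_vectors_give_p_one(self):
        assert sc.wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_symmetric_in_arguments(self):
        x, y = [0.1, 0.7, 0.3], [0.9, 0.2, 0.5, 0.8]
        assert sc.wilcoxon_rank_sum(x, y) == pytest.approx(sc.wilcoxon_rank_sum(y, x))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sc.wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle_for_all_small_partitions(self):
        # every split of 1..n into two non-empty untied groups, n <= 7,
        # plus spot checks at n = 10
        for n in range(2, 8):
            values = list(range(1, n + 1))
            for nx in range(1, n):
                for xs in itertools.combinations(values, nx):
                    ys = [v for v in values if v not in xs]
                    assert sc.wilcoxon_rank_sum(list(xs), ys) == pytest.approx(
                        ranksum_p_enumeration(list(xs), ys), abs=1e-12
                    ), (xs, ys)
        rng = np.random.default_rng(0)
        for _ in range(20):
            pool = rng.permutation(10) + rng.random()  # untied floats
            nx = int(rng.integers(1, 10))
            x, y = list(pool[:nx]), list(pool[nx:])
            assert sc.wilcoxon_rank_sum(x, y) == pytest.approx(
                ranksum_p_enumeration(x, y), abs=1e-12
            )


class TestBH:
    def test_hand_computed_stepup(self):
        assert sc.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert sc.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert sc.bh_fdr([0.01] * 7) == pytest.approx([0.01] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.bh_fdr([0.5, 1.5])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_textbook_stepup_and_is_bounded(self, ps):
        adj = sc.bh_fdr(ps)
        assert np.all(adj <= 1 + 1e-12)
        assert adj == pytest.approx(bh_stepup(ps), abs=1e-12)


class TestFisherEnrichment:
    def test_two_by_two_enumeration_value(self):
        # [[2,0],[0,2]]: one-sided p = 1/6
        ann = CompoundAnnotation({c: {"cls"} for c in ["a", "b"]})
        bg = {"a", "b", "c", "d"}
        table = sc.class_enrichment({"a", "b"}, ann, bg)
        row = table[table["class"] == "cls"].iloc[0]
        assert row["p"] == pytest.approx(1 / 6, abs=1e-12)

    def test_candidates_equal_background_never_enriched(self):
        ann = CompoundAnnotation({"a": {"x"}, "b": {"y"}})
        bg = {"a", "b"}
        table = sc.class_enrichment(bg, ann, bg)
        assert (table["p"] == 1.0).all()

    def test_planted_class_bias_ranks_first(self):
        ann = CompoundAnnotation(
            {f"c{i}": {"planted" if i < 5 else "other"} for i in range(20)}
        )
        bg = {f"c{i}" for i in range(20)}
        table = sc.class_enrichment({"c0", "c1", "c2", "c3", "c4"}, ann, bg)
        assert table.iloc[0]["class"] == "planted"

    def test_candidates_outside_background_rejected(self):
        with pytest.raises(ValueError):
            sc.class_enrichment({"zz"}, CompoundAnnotation({}), {"a"})

    def test_matches_hypergeometric_for_all_small_margins(self):
        for a in range(0, 5):
            for b in range(0, 5):
                for c in range(0, 5):
                    for d in range(0, 5):
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        if a + b + c + d > 8:
                            continue
                        import scipy.stats

                        _, p = scipy.stats.fisher_exact([[a, b], [c, d]], "greater")
                        assert p == pytest.approx(
                            fisher_p_hypergeom(a, b, c, d, "greater"), abs=1e-10
                        ), (a, b, c, d)


def abm_result(compound, target_changes, other_changes):
    rows = []
    for i, v in enumerate(target_changes):
        rows.append({"replicate": i, "species_id": "T", "relative_change": v})
    for i, v in enumerate(other_changes):
        rows.append({"replicate": i, "species_id": "O", "relative_change": v})
    return AbmRunResult(compound=compound, trajectory=pd.DataFrame(),
                        relative_change=pd.DataFrame(rows))


class TestAbmSelection:
    def test_median_toward_other_not_selected_despite_significance(self):
        res = {"c": abm_result("c", [1, 2, 3], [4, 5, 6])}
        sel, stats = sc.screen_abm_stats(res, "T", "O", alpha=0.15)
        assert stats.iloc[0]["p"] == pytest.approx(0.1)
        assert sel == set()

    def test_identical_vectors_not_selected(self):
        res = {"c": abm_result("c", [1.0, 1.0], [1.0, 1.0])}
        sel, stats = sc.screen_abm_stats(res, "T", "O")
        assert stats.iloc[0]["p"] == 1.0 and sel == set()

    def test_selected_requires_median_and_fdr(self):
        res = {
            "good": abm_result("good", [4, 5, 6, 7], [1, 2, 3, 3.5]),
            "null": abm_result("null", [1, 2, 3, 4], [1.5, 2.5, 3.5, 2.8]),
        }
        sel, stats = sc.screen_abm_stats(res, "T", "O", alpha=0.06)
        assert "null" not in sel
        row = stats.set_index("compound").loc["good"]
        assert row["median_target"] > row["median_other"]


class TestSingleFbaScreen:
    def test_relative_change_and_cutoff(self):
        model = generate_species_model(SpeciesSpec("s", {"A": 1.0, "S": 0.5}))
        medium = Medium({"A": 10.0, "S": 0.0})
        sel, recs = sc.screen_single_fba(model, medium, ["S", "A"], dose=10.0)
        by = {r.compound: r for r in recs}
        # mu_base = 10; S: +5 -> 0.5 selected; A: +10 -> 1.0 selected
        assert by["S"].relative_change == pytest.approx(0.5)
        assert sel == {"S", "A"}

    def test_small_change_not_selected(self):
        model = generate_species_model(SpeciesSpec("s", {"A": 1.0, "S": 0.5}))
        medium = Medium({"A": 10.0})
        sel, recs = sc.screen_single_fba(model, medium, ["S"], dose=0.1)
        # change = 0.05/10 = 0.005 <= 0.01
        assert sel == set()
        assert recs[0].relative_change == pytest.approx(0.005)

    def test_zero_baseline_excluded_not_crashed(self):
        model = generate_species_model(SpeciesSpec("s", {"S": 1.0}))
        sel, recs = sc.screen_single_fba(model, Medium({}), ["S"])
        assert sel == set() and recs[0].relative_change is None


class TestIntersectConfirm:
    def test_set_algebra_and_confirmation(self):
        sets = {"m1": {"a", "b", "c"}, "m2": {"b", "c"}, "m3": {"b", "c", "d"}}
        biolog = BiologTable({"b": (0.4, 0.1), "c": (0.15, 0.1)})
        res = sc.intersect_and_confirm(sets, biolog)
        assert res.intersection == {"b", "c"}
        assert res.biolog_confirmed == {"b"}
        assert res.not_assayed == set()

    def test_not_assayed_reported_separately(self):
        res = sc.intersect_and_confirm({"m": {"x", "y"}}, BiologTable({"x": (0.4, 0.1)}))
        assert res.biolog_confirmed == {"x"}
        assert res.not_assayed == {"y"}

    def test_empty_method_set_empties_intersection(self):
        res = sc.intersect_and_confirm({"m1": {"a"}, "m2": set()}, BiologTable({}))
        assert res.intersection == set()


class TestHostAnalysis:
    def test_expectation_formula(self):
        d = sc.HostColonizationData(0.6, 0.75, 0.5)
        assert sc.expected_worm_proportion(d) == pytest.approx(0.625)

    def test_no_supplementation_effect_identity(self):
        d = sc.HostColonizationData(0.6, 0.6, 0.5)
        assert sc.expected_worm_proportion(d) == pytest.approx(0.5)

    def test_no_host_filtering_identity(self):
        d = sc.HostColonizationData(0.6, 0.75, 0.6)
        assert sc.expected_worm_proportion(d) == pytest.approx(0.75)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            sc.expected_worm_proportion(sc.HostColonizationData(0.0, 0.7, 0.5))

    def test_chi_square_observed_equals_expected(self):
        chi2, df, p = sc.chisq_observed_vs_expected([50, 50], [0.5, 0.5])
        assert chi2 == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_chi_square_hand_value(self):
        chi2, df, p = sc.chisq_observed_vs_expected([30, 70], [0.5, 0.5])
        assert chi2 == pytest.approx(16.0) and df == 1

    def test_reported_statistic_reproduces_printed_p(self):
        # survival function at chi2 = 10.244, df = 1
        import scipy.stats

        p = scipy.stats.chi2.sf(10.244, 1)
        assert p == pytest.approx(0.0013, abs=1e-4)
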