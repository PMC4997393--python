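"""Candidate ranking, blend enumeration and mapping application."""

import itertools

import numpy as np
import pytest

from bopmap.mapping import (
    DistanceConfig,
    apply_mappings,
    blend_panel,
    distance,
    enumerate_blends,
    pct_diff,
    rank_single,
    recipe_mapping,
)
from bopmap.model import Allocation, MappingResult, RANKING_NUTRIENTS

from conftest import make_branded, make_generic, make_panel


class TestPctDiff:
    @pytest.mark.parametrize("branded, reference, expected", [
        (100.0, 100.0, 0.0),
        (100.0, 110.0, 10.0),
        (100.0, 90.0, -10.0),
        (0.0, 42.0, 500.0),   # diet-drink pattern: 4200% clamps to the cap
        (42.0, 0.0, -100.0),
    ])
    def test_signed_percentage(self, branded, reference, expected):
        assert pct_diff(branded, reference) == pytest.approx(expected)

    def test_missing_value_incomparable(self):
        assert pct_diff(None, 10.0) is None
        assert pct_diff(10.0, None) is None

    def test_epsilon_floors_denominator(self):
        # branded 0.05 below epsilon 0.1: denominator is epsilon
        assert pct_diff(0.05, 0.15, epsilon=0.1, cap=1e9) == pytest.approx(100.0)


class TestDistance:
    def test_identical_panels_zero(self):
        p = make_panel(energy_kcal=100, fat_g=10, protein_g=5, carb_g=20)
        assert distance(p, p) == 0.0

    def test_hand_arithmetic_sum(self):
        branded = make_panel(energy_kcal=100, fat_g=10, protein_g=5, carb_g=20)
        candidate = make_panel(energy_kcal=110, fat_g=11, protein_g=5, carb_g=20)
        assert distance(branded, candidate) == pytest.approx(20.0)

    def test_partial_panel_rescaled_to_full_sum(self):
        branded = make_panel(energy_kcal=100)
        candidate = make_panel(energy_kcal=105)
        # mean |pct_diff| = 5 over the single comparable nutrient, x4
        assert distance(branded, candidate) == pytest.approx(20.0)

    def test_no_shared_nutrient_incomparable(self):
        assert distance(make_panel(energy_kcal=100), make_panel(fibre_g=3)) is None


def naive_rank(branded, generics, epsilon=0.1, cap=500.0):
    """Independent brute-force ranking oracle (plain loops, no reuse)."""
    rows = []
    for g in generics:
        diffs = []
        for key in ("energy_kcal", "fat_g", "protein_g", "carb_g"):
            bv, gv = branded.panel.get(key), g.panel.get(key)
            if bv is None or gv is None:
                continue
            d = 100.0 * (gv - bv) / max(bv, epsilon)
            diffs.append(min(cap, abs(d)) if abs(d) <= cap else cap)
        if diffs:
            rows.append((sum(diffs) / len(diffs) * 4.0, g.code))
    return [code for _, code in sorted(rows)]


class TestRankSingle:
    def test_exact_copy_ranks_first_with_zero_distance(self, small_generics):
        parent = small_generics[2]  # bread
        branded = make_branded("B1", "branded bread", group="bread")
        branded.panel = parent.panel.copy()
        results = rank_single(branded, small_generics, top_k=3)
        assert results[0].allocations[0].generic_code == parent.code
        assert results[0].distance == 0.0
        assert [r.rank for r in results] == [1, 2, 3]

    def test_tie_broken_by_code(self):
        ga = make_generic("G_A", energy_kcal=110, fat_g=10, protein_g=5, carb_g=20)
        gb = make_generic("G_B", energy_kcal=110, fat_g=10, protein_g=5, carb_g=20)
        branded = make_branded("B1", "x", energy_kcal=100, fat_g=10,
                               protein_g=5, carb_g=20)
        results = rank_single(branded, [gb, ga], top_k=2)
        assert [r.allocations[0].generic_code for r in results] == ["G_A", "G_B"]

    def test_top_k_larger_than_catalog(self, small_generics):
        branded = make_branded("B1", "x", energy_kcal=100, fat_g=10,
                               protein_g=5, carb_g=20)
        assert len(rank_single(branded, small_generics[:3], top_k=5)) == 3

    def test_all_incomparable_warns_and_returns_empty(self, small_generics):
        branded = make_branded("B1", "label-free item")  # empty panel
        with pytest.warns(UserWarning):
            assert rank_single(branded, small_generics) == []

    def test_empty_generics_error(self):
        with pytest.raises(ValueError):
            rank_single(make_branded("B1", "x"), [])

    def test_ordering_matches_bruteforce_oracle(self):
        """Dual-route check over seeded random panels, <= 20 generics."""
        rng = np.random.default_rng(123)
        for trial in range(10):
            n = int(rng.integers(3, 21))
            generics = [
                make_generic(f"G{j:02d}",
                             energy_kcal=float(rng.uniform(10, 800)),
                             fat_g=float(rng.uniform(0, 60)),
                             protein_g=float(rng.uniform(0, 40)),
                             carb_g=float(rng.uniform(0, 90)))
                for j in range(n)
            ]
            branded = make_branded("B1", "probe",
                                   energy_kcal=float(rng.uniform(10, 800)),
                                   fat_g=float(rng.uniform(0, 60)),
                                   protein_g=float(rng.uniform(0, 40)),
                                   carb_g=float(rng.uniform(0, 90)))
            got = [r.allocations[0].generic_code
                   for r in rank_single(branded, generics, top_k=n)]
            assert got == naive_rank(branded, generics)


class TestEnumerateBlends:
    def test_one_by_one_gives_eleven_unique_candidates(self, small_generics):
        branded = make_branded("B1", "x", energy_kcal=100, fat_g=5,
                               protein_g=5, carb_g=20)
        out = enumerate_blends(branded, [small_generics[0]], [small_generics[1]],
                               top_k=20)
        assert out.evaluations == 11
        assert out.unique_candidates == 11  # 9 interior blends + 2 singles

    def test_two_by_three_evaluation_count(self, small_generics):
        branded = make_branded("B1", "x", energy_kcal=100, fat_g=5,
                               protein_g=5, carb_g=20)
        out = enumerate_blends(branded, small_generics[:2], small_generics[2:5])
        assert out.evaluations == 2 * 3 * 11

    def test_unique_count_matches_bruteforce_enumeration(self, small_generics):
        """Independent oracle: enumerate (pair, split) tuples and collapse
        degenerate splits to their single-food identity by hand."""
        a_list, b_list = small_generics[:2], small_generics[2:5]
        seen = set()
        for a, b in itertools.product(a_list, b_list):
            for p in range(0, 101, 10):
                if p == 100:
                    seen.add(((a.code, 100.0),))
                elif p == 0:
                    seen.add(((b.code, 100.0),))
                else:
                    seen.add(tuple(sorted([(a.code, float(p)),
                                           (b.code, float(100 - p))])))
        branded = make_branded("B1", "x", energy_kcal=100, fat_g=5,
                               protein_g=5, carb_g=20)
        out = enumerate_blends(branded, a_list, b_list, top_k=100)
        assert out.unique_candidates == len(seen)

    def test_exact_blend_recovered_at_rank_one(self, small_generics):
        a, b = small_generics[3], small_generics[4]  # cheese, breaded fish
        branded = make_branded("B1", "cheesy fish bake", group="fish")
        for key in RANKING_NUTRIENTS:
            branded.panel.set(key, 0.4 * a.panel.get(key) + 0.6 * b.panel.get(key))
        out = enumerate_blends(branded, [a], [b])
        best = out.results[0]
        assert best.distance == pytest.approx(0.0, abs=1e-9)
        assert {(al.generic_code, al.percent) for al in best.allocations} \
            == {(a.code, 40.0), (b.code, 60.0)}

    def test_empty_list_error(self, small_generics):
        with pytest.raises(ValueError):
            enumerate_blends(make_branded("B1", "x"), [], small_generics)


class TestBlendPanel:
    def test_single_allocation_is_identity(self, small_generics):
        g = small_generics[2]
        blended = blend_panel([Allocation(g.code, 100.0)], {g.code: g})
        for key in RANKING_NUTRIENTS:
            assert blended.get(key) == pytest.approx(g.panel.get(key))
        assert blended.micronutrients == pytest.approx(g.panel.micronutrients)

    def test_linear_micronutrient_blend(self):
        a = make_generic("GA", micronutrients={"iron_mg": 2.0})
        b = make_generic("GB", micronutrients={"iron_mg": 4.0})
        blended = blend_panel([Allocation("GA", 50.0), Allocation("GB", 50.0)],
                              {"GA": a, "GB": b})
        assert blended.micronutrients["iron_mg"] == pytest.approx(3.0)

    def test_missing_constituent_nutrient_propagates(self):
        a = make_generic("GA", micronutrients={"vitamin_c_mg": 10.0})
        b = make_generic("GB")  # no vitamin C
        blended = blend_panel([Allocation("GA", 50.0), Allocation("GB", 50.0)],
                              {"GA": a, "GB": b})
        assert "vitamin_c_mg" not in blended.micronutrients

    def test_blend_linearity_property(self):
        rng = np.random.default_rng(5)
        a = make_generic("GA", energy_kcal=123.4, fat_g=3.21, protein_g=9.9,
                         carb_g=44.0, micronutrients={"iron_mg": 1.7})
        b = make_generic("GB", energy_kcal=321.0, fat_g=17.0, protein_g=2.2,
                         carb_g=5.5, micronutrients={"iron_mg": 0.3})
        index = {"GA": a, "GB": b}
        for p in rng.uniform(1, 99, size=20):
            blended = blend_panel([Allocation("GA", p), Allocation("GB", 100 - p)],
                                  index)
            for key in (*RANKING_NUTRIENTS, "iron_mg"):
                expected = (p * a.panel.get(key) + (100 - p) * b.panel.get(key)) / 100
                assert blended.get(key) == pytest.approx(expected, abs=1e-9)

    def test_unresolvable_code_named_in_error(self, small_generics):
        with pytest.raises(KeyError, match="G_MISSING"):
            blend_panel([Allocation("G_MISSING", 100.0)], {})


class TestApplyMappings:
    def test_label_macros_never_overwritten(self, small_generics):
        # diet drink: label energy 1 kcal, mapped to sugary generic cola
        item = make_branded("B1", "diet cola", group="soft drinks",
                            energy_kcal=1.0, sugars_g=0.0)
        mapping = MappingResult("B1", [Allocation("G_COLA", 100.0)],
                                distance=500.0)
        out = apply_mappings([item], [mapping], small_generics)
        enriched = out.catalog[0]
        assert enriched.panel.energy_kcal == 1.0
        assert enriched.panel.sugars_g == 0.0
        assert enriched.panel.micronutrients["iron_mg"] == pytest.approx(0.01)

    def test_description_only_fills_macros_too(self, small_generics):
        item = make_branded("B1", "lager no label")
        mapping = MappingResult("B1", [Allocation("G_BEER", 100.0)],
                                distance=None, method="description_only")
        out = apply_mappings([item], [mapping], small_generics)
        assert out.catalog[0].panel.energy_kcal == pytest.approx(40.0)
        assert out.catalog[0].panel.micronutrients["iron_mg"] == pytest.approx(0.02)

    def test_unmapped_item_passes_through(self, small_generics):
        item = make_branded("B1", "novel item", energy_kcal=50.0)
        out = apply_mappings([item], [], small_generics)
        assert out.unmapped == ["B1"]
        assert out.catalog[0].panel.energy_kcal == 50.0
        assert out.catalog[0].panel.micronutrients == {}

    def test_unknown_item_id_error(self, small_generics):
        mapping = MappingResult("B_NOPE", [Allocation("G_BEER", 100.0)], 0.0)
        with pytest.raises(KeyError, match="B_NOPE"):
            apply_mappings([make_branded("B1", "x")], [mapping], small_generics)


class TestRecipeMapping:
    def test_many_ingredient_recipe_accepted(self, small_generics):
        # a ready-meal style recipe across many allocations
        generics = [make_generic(f"G{i:02d}", energy_kcal=100 + i)
                    for i in range(23)]
        allocations = [(f"G{i:02d}", 100.0 / 23) for i in range(23)]
        branded = make_branded("B1", "korma ready meal", energy_kcal=150.0,
                               fat_g=8.0, protein_g=6.0, carb_g=14.0)
        result = recipe_mapping(branded, allocations, generics)
        assert len(result.allocations) == 23
        assert result.method == "manual_recipe"
        assert sum(a.percent for a in result.allocations) == pytest.approx(100.0)

    def test_slightly_off_sum_renormalized(self, small_generics):
        branded = make_branded("B1", "x", energy_kcal=100, fat_g=5,
                               protein_g=5, carb_g=10)
        result = recipe_mapping(branded, [("G_BEER", 50.2), ("G_COLA", 50.2)],
                                small_generics)
        assert sum(a.percent for a in result.allocations) == pytest.approx(100.0)

    def test_far_off_sum_rejected(self, small_generics):
        with pytest.raises(ValueError):
            recipe_mapping(make_branded("B1", "x"),
                           [("G_BEER", 45.0), ("G_COLA", 45.0)], small_generics)
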