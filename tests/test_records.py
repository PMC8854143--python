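"""Recipe disaggregation, food-group classification and age splitting."""

from collections import defaultdict, deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietgap.conversions import ConversionConfig, FormFactor
from dietgap.records import (
    Cohort,
    GroupMapping,
    MappedIngredient,
    Recipe,
    RecipeCycleError,
    RecipeDB,
    RecordDay,
    UnknownFoodError,
    classify_day,
    expand_to_ingredients,
    split_by_age_group,
)


def day(entries, child="c1", idx=1, weekday="Mon", age=4.0):
    return RecordDay(child_id=child, day_index=idx, weekday=weekday, age_years=age, entries=tuple(entries))


class TestExpand:
    def test_base_ingredient_identity(self):
        out = expand_to_ingredients(day([("apple", 150.0)]), RecipeDB())
        assert out == [("apple", 150.0)]

    def test_nested_shares(self):
        db = RecipeDB(
            [
                Recipe("P", (("A", 0.6), ("B", 0.4))),
                Recipe("B", (("C", 0.5), ("D", 0.5))),
            ]
        )
        out = dict(expand_to_ingredients(day([("P", 100.0)]), db))
        assert out == pytest.approx({"A": 60.0, "C": 20.0, "D": 20.0})

    def test_duplicate_entries_summed_before_expansion(self):
        db = RecipeDB([Recipe("P", (("A", 0.5), ("B", 0.5)))])
        out = dict(expand_to_ingredients(day([("P", 40.0), ("P", 60.0)]), db))
        assert out == pytest.approx({"A": 50.0, "B": 50.0})

    def test_cycle_detected_and_named(self):
        with pytest.raises(RecipeCycleError, match="A"):
            RecipeDB([Recipe("A", (("B", 1.0),)), Recipe("B", (("A", 1.0),))])
        with pytest.raises(RecipeCycleError, match="self"):
            Recipe("A", (("A", 1.0),))

    def test_unknown_leaf_code_named(self):
        with pytest.raises(UnknownFoodError, match="mystery"):
            expand_to_ingredients(day([("mystery", 10.0)]), RecipeDB(), base_codes={"apple"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_mass_conservation_random_dags(self, data):
        """Expansion conserves mass on random layered acyclic recipe graphs;
        checked against an independent non-recursive breadth-first oracle."""
        n_base = data.draw(st.integers(2, 5))
        n_prod = data.draw(st.integers(1, 6))
        codes = [f"b{i}" for i in range(n_base)]
        recipes = []
        for k in range(n_prod):
            m = data.draw(st.integers(1, min(3, len(codes))))
            comps = data.draw(
                st.lists(st.sampled_from(codes), min_size=m, max_size=m, unique=True)
            )
            raw = data.draw(
                st.lists(st.floats(0.05, 1.0), min_size=m, max_size=m)
            )
            total = sum(raw)
            shares = [r / total for r in raw]
            # force exact unit sum
            shares[-1] = 1.0 - sum(shares[:-1])
            recipes.append(Recipe(f"p{k}", tuple(zip(comps, shares))))
            codes.append(f"p{k}")
        db = RecipeDB(recipes)
        entries = [
            (data.draw(st.sampled_from(codes)), data.draw(st.floats(1.0, 500.0)))
            for _ in range(data.draw(st.integers(1, 6)))
        ]
        out = expand_to_ingredients(day(entries), db)

        # oracle: queue-based breadth-first expansion
        oracle: dict[str, float] = defaultdict(float)
        queue = deque(entries)
        while queue:
            code, amount = queue.popleft()
            r = db.get(code)
            if r is None:
                oracle[code] += amount
            else:
                queue.extend((c, amount * s) for c, s in r.components)

        assert sum(a for _, a in out) == pytest.approx(sum(a for _, a in entries), rel=1e-9)
        got = dict(out)
        assert set(got) == set(oracle)
        for code in oracle:
            assert got[code] == pytest.approx(oracle[code], rel=1e-9)


@pytest.fixture()
def tiny_mapping():
    return GroupMapping(
        [
            MappedIngredient("potato", "tubers", kcal_per_g=0.8),
            MappedIngredient("dark_macaroni", "whole_grains", kcal_per_g=1.5),
            MappedIngredient("butter", "dairy", dairy_category="butter", kcal_per_g=7.2),
            MappedIngredient("lard", "saturated_fats", kcal_per_g=9.0),
            MappedIngredient("palm_oil", "saturated_fats", kcal_per_g=8.8),
            MappedIngredient("gum", "EXCLUDED", kcal_per_g=1.6),
            MappedIngredient(
                "flavoured_yoghurt",
                "dairy",
                dairy_category="yoghurt",
                sugar_group="sweetened_dairy",
                total_sugar_per_g=0.12,
                kcal_per_g=0.9,
            ),
            MappedIngredient("sugar", "added_sugars", sugar_group="sugar", total_sugar_per_g=1.0, kcal_per_g=4.0),
        ]
    )


class TestClassify:
    conv = ConversionConfig(form=FormFactor({"dark_macaroni": 0.42}))

    def classify(self, ingredients, mapping, conv=None):
        return classify_day(day([]), ingredients, mapping, conv or self.conv)

    def test_direct_mapping(self, tiny_mapping):
        row = self.classify([("potato", 100.0)], tiny_mapping)
        assert row.grams["tubers"] == pytest.approx(100.0)

    def test_dark_macaroni_counts_as_whole_grain_in_dry_form(self, tiny_mapping):
        row = self.classify([("dark_macaroni", 100.0)], tiny_mapping)
        assert row.grams["whole_grains"] == pytest.approx(42.0)
        assert sum(row.grams.values()) == pytest.approx(42.0)

    def test_excluded_contributes_nothing_but_energy(self, tiny_mapping):
        row = self.classify([("gum", 50.0)], tiny_mapping)
        assert all(v == 0.0 for v in row.grams.values())
        assert row.energy_kcal == pytest.approx(80.0)

    def test_dairy_fat_routes_to_dairy_lard_to_saturated(self, tiny_mapping):
        row = self.classify([("butter", 10.0), ("lard", 5.0), ("palm_oil", 5.0)], tiny_mapping)
        assert row.grams["dairy"] == pytest.approx(65.0)  # butter x 6.5 milk equivalents
        assert row.grams["saturated_fats"] == pytest.approx(10.0)

    def test_sugar_carrier_counts_in_source_group_and_added_sugars(self, tiny_mapping):
        row = self.classify([("flavoured_yoghurt", 100.0)], tiny_mapping)
        assert row.grams["dairy"] == pytest.approx(100.0)
        assert row.grams["added_sugars"] == pytest.approx(100.0 * 0.12 * 0.6)

    def test_subtract_added_sugar_from_source_flag(self, tiny_mapping):
        conv = ConversionConfig(subtract_added_sugar_from_source=True)
        row = self.classify([("flavoured_yoghurt", 100.0)], tiny_mapping, conv)
        assert row.grams["dairy"] == pytest.approx(100.0 - 7.2)
        assert row.grams["added_sugars"] == pytest.approx(7.2)

    def test_pure_sugar_counts_only_once(self, tiny_mapping):
        row = self.classify([("sugar", 30.0)], tiny_mapping)
        assert row.grams["added_sugars"] == pytest.approx(30.0)
        assert sum(row.grams.values()) == pytest.approx(30.0)

    def test_unmapped_code_raises(self, tiny_mapping):
        with pytest.raises(UnknownFoodError, match="mystery"):
            self.classify([("mystery", 10.0)], tiny_mapping)


class TestAgeSplit:
    def make(self, ages):
        days = [
            day([("x", 1.0)], child=f"c{i}", idx=j + 1, age=a)
            for i, child_ages in enumerate(ages)
            for j, a in enumerate(child_ages)
        ]
        children = {f"c{i}": "girl" for i in range(len(ages))}
        return Cohort(children=children, days=days)

    def test_child_straddling_boundary_in_both(self):
        young, old = split_by_age_group(self.make([[4.9, 5.1]]))
        assert [d.age_years for d in young.days] == [4.9]
        assert [d.age_years for d in old.days] == [5.1]
        assert set(young.children) == set(old.children) == {"c0"}

    def test_all_young(self):
        young, old = split_by_age_group(self.make([[3.5, 3.6]]))
        assert len(young.days) == 2 and not old.days

    def test_out_of_range_days_dropped(self):
        young, old = split_by_age_group(self.make([[2.9, 7.0, 3.0, 6.99]]))
        assert sorted(d.age_years for d in young.days) == [3.0]
        assert sorted(d.age_years for d in old.days) == [6.99]

    def test_partition_of_generated_cohort(self, cohort_bundle):
        cohort = cohort_bundle[0]
        young, old = split_by_age_group(cohort)
        retained = [d for d in cohort.days if 3.0 <= d.age_years < 7.0]
        assert len(young.days) + len(old.days) == len(retained)
        both = set(young.children) & set(old.children)
        straddlers = {
            c
            for c in cohort.children
            if any(d.child_id == c and 3.0 <= d.age_years < 5.0 for d in cohort.days)
            and any(d.child_id == c and 5.0 <= d.age_years < 7.0 for d in cohort.days)
        }
        assert both == straddlers
        assert straddlers  # the two-round design creates boundary crossers


class TestValidation:
    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            day([("apple", -1.0)])

    def test_share_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            Recipe("P", (("A", 0.6), ("B", 0.3)))

    def test_cohort_requires_known_children(self):
        with pytest.raises(ValueError, match="unknown children"):
            Cohort(children={}, days=[day([("a", 1.0)])])
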