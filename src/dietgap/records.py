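"""Food-record data model, recipe disaggregation and food-group classification.

Food records arrive as child-days of (food code, grams consumed).  Composite
dishes and industrial products carry recipes — directed acyclic
product -> ingredient decompositions with mass shares — which are expanded
recursively until only base ingredients remain.  Base ingredients are then
classified into the reference diet's food groups, applying the measurement
conventions from :mod:`dietgap.conversions` (milk equivalents, added-sugar
estimation, raw/dry form conversion).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .conversions import ConversionConfig, convert_form, estimate_added_sugars

__all__ = [
    "FOOD_GROUPS",
    "EXCLUDED",
    "WEEKDAYS",
    "WEEKEND_DAYS",
    "FoodRef",
    "Recipe",
    "RecipeDB",
    "RecordDay",
    "Cohort",
    "MappedIngredient",
    "GroupMapping",
    "GroupIntakeRow",
    "RecipeCycleError",
    "UnknownFoodError",
    "expand_to_ingredients",
    "classify_day",
    "split_by_age_group",
]

#: Reference-diet food groups in the conventional table order (aggregate red
#: meat is derived downstream as beef_lamb + pork and is not a mapping group).
FOOD_GROUPS: tuple[str, ...] = (
    "whole_grains",
    "tubers",
    "vegetables",
    "fruits",
    "dairy",
    "beef_lamb",
    "pork",
    "poultry",
    "eggs",
    "fish",
    "legumes",
    "nuts",
    "saturated_fats",
    "unsaturated_oils",
    "added_sugars",
)

EXCLUDED = "EXCLUDED"

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
WEEKEND_DAYS = frozenset({"Sat", "Sun"})


class RecipeCycleError(ValueError):
    """The recipe graph contains a cycle (a product is its own ingredient)."""


class UnknownFoodError(KeyError):
    """A food code has neither a recipe nor a base-ingredient mapping."""


@dataclass(frozen=True)
class FoodRef:
    code: str
    name: str = ""
    is_base: bool = True


@dataclass(frozen=True)
class Recipe:
    """Mass-share decomposition of one product into direct components.

    Components may themselves be products (nested recipes).  Shares are
    fractions of product mass, strictly positive and summing to 1.
    """

    product_code: str
    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"recipe for {self.product_code!r} has no components")
        total = 0.0
        for code, share in self.components:
            if code == self.product_code:
                raise RecipeCycleError(
                    f"product {self.product_code!r} lists itself as an ingredient"
                )
            if not share > 0:
                raise ValueError(
                    f"recipe {self.product_code!r}: share for {code!r} must be > 0"
                )
            total += share
        if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=1e-6):
            raise ValueError(
                f"recipe {self.product_code!r}: mass shares sum to {total!r}, not 1"
            )


class RecipeDB:
    """Recipe collection with acyclicity enforced at construction."""

    def __init__(self, recipes: Iterable[Recipe] = ()) -> None:
        self._recipes: dict[str, Recipe] = {}
        for r in recipes:
            if r.product_code in self._recipes:
                raise ValueError(f"duplicate recipe for {r.product_code!r}")
            self._recipes[r.product_code] = r
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        colour: dict[str, int] = defaultdict(int)

        def visit(code: str, path: list[str]) -> None:
            if colour[code] == BLACK or code not in self._recipes:
                return
            if colour[code] == GREY:
                cyc = path[path.index(code):] + [code]
                raise RecipeCycleError("recipe cycle: " + " -> ".join(cyc))
            colour[code] = GREY
            path.append(code)
            for comp, _ in self._recipes[code].components:
                visit(comp, path)
            path.pop()
            colour[code] = BLACK

        for code in list(self._recipes):
            visit(code, [])

    def __contains__(self, code: str) -> bool:
        return code in self._recipes

    def __len__(self) -> int:
        return len(self._recipes)

    def get(self, code: str) -> Recipe | None:
        return self._recipes.get(code)

    def product_codes(self) -> list[str]:
        return sorted(self._recipes)


@dataclass(frozen=True)
class RecordDay:
    """One child-day of consumed foods in grams."""

    child_id: str
    day_index: int
    weekday: str
    age_years: float
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.weekday not in WEEKDAYS:
            raise ValueError(f"weekday must be one of {WEEKDAYS}, got {self.weekday!r}")
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        for code, amount in self.entries:
            if amount < 0:
                raise ValueError(
                    f"negative amount {amount} for {code!r} "
                    f"(child {self.child_id}, day {self.day_index})"
                )

    @property
    def is_weekend(self) -> bool:
        return self.weekday in WEEKEND_DAYS


@dataclass
class Cohort:
    """A set of children (with sex) and their record days."""

    children: dict[str, str]  # child_id -> 'girl' | 'boy'
    days: list[RecordDay]

    def __post_init__(self) -> None:
        for sex in self.children.values():
            if sex not in ("girl", "boy"):
                raise ValueError(f"sex must be 'girl' or 'boy', got {sex!r}")
        missing = {d.child_id for d in self.days} - set(self.children)
        if missing:
            raise ValueError(f"record days reference unknown children: {sorted(missing)}")

    def n_children(self) -> int:
        return len({d.child_id for d in self.days})


@dataclass(frozen=True)
class MappedIngredient:
    """Classification + conversion metadata for one base ingredient."""

    code: str
    group: str  # one of FOOD_GROUPS or EXCLUDED
    name: str = ""
    dairy_category: str | None = None  # required when group == 'dairy'
    sugar_group: str | None = None
    total_sugar_per_g: float = 0.0
    kcal_per_g: float = 0.0
    is_representative: bool = False

    def __post_init__(self) -> None:
        if self.group != EXCLUDED and self.group not in FOOD_GROUPS:
            raise ValueError(f"{self.code!r}: unknown food group {self.group!r}")
        if self.group == "dairy" and not self.dairy_category:
            raise ValueError(f"{self.code!r}: dairy ingredient needs a dairy_category")
        if not 0.0 <= self.total_sugar_per_g <= 1.0:
            raise ValueError(f"{self.code!r}: total_sugar_per_g outside [0, 1]")


class GroupMapping:
    """Base-ingredient -> food-group mapping with conversion metadata."""

    def __init__(self, ingredients: Iterable[MappedIngredient]) -> None:
        self._map: dict[str, MappedIngredient] = {}
        for ing in ingredients:
            if ing.code in self._map:
                raise ValueError(f"duplicate mapping for ingredient {ing.code!r}")
            self._map[ing.code] = ing

    def __contains__(self, code: str) -> bool:
        return code in self._map

    def __len__(self) -> int:
        return len(self._map)

    def get(self, code: str) -> MappedIngredient:
        try:
            return self._map[code]
        except KeyError:
            raise UnknownFoodError(f"ingredient {code!r} is not in the group mapping") from None

    def codes(self) -> set[str]:
        return set(self._map)


@dataclass
class GroupIntakeRow:
    """Per-group grams for one child-day, plus total energy.

    Dairy grams are in milk equivalents; added sugars are the estimated
    added-sugar mass; other groups are raw/dry-form grams.  Energy covers
    the whole recorded diet, including foods excluded from the groups.
    """

    child_id: str
    day_index: int
    weekday: str
    age_years: float
    grams: dict[str, float] = field(default_factory=dict)
    energy_kcal: float = 0.0

    @property
    def is_weekend(self) -> bool:
        return self.weekday in WEEKEND_DAYS


def expand_to_ingredients(
    day: RecordDay,
    recipes: RecipeDB,
    base_codes: set[str] | None = None,
) -> list[tuple[str, float]]:
    """Recursively expand a day's foods to base-ingredient amounts.

    Any code without a recipe is treated as a base ingredient; when
    ``base_codes`` is given, leaf codes outside it raise
    :class:`UnknownFoodError`.  Duplicate entries of the same food are summed
    before expansion.  Total output mass equals total input mass (each
    product's mass is distributed over its components by mass share).
    """
    pooled: dict[str, float] = defaultdict(float)
    for code, amount in day.entries:
        pooled[code] += amount

    out: dict[str, float] = defaultdict(float)

    def descend(code: str, amount: float) -> None:
        recipe = recipes.get(code)
        if recipe is None:
            if base_codes is not None and code not in base_codes:
                raise UnknownFoodError(
                    f"food code {code!r} has no recipe and is not a known base ingredient "
                    f"(child {day.child_id}, day {day.day_index})"
                )
            out[code] += amount
            return
        for comp, share in recipe.components:
            descend(comp, amount * share)

    for code, amount in pooled.items():
        if amount > 0:
            descend(code, amount)
    return sorted(out.items())


def classify_day(
    day: RecordDay,
    ingredients: Sequence[tuple[str, float]],
    mapping: GroupMapping,
    conversions: ConversionConfig,
) -> GroupIntakeRow:
    """Classify a day's base-ingredient amounts into food-group grams.

    Routing rules:

    * ``EXCLUDED`` ingredients contribute energy only.
    * Every ingredient with sugar metadata contributes its estimated added
      sugar to ``added_sugars``; by default that mass is *also* counted in
      the source group (``subtract_added_sugar_from_source`` flips this).
    * Pure sugar sources (group ``added_sugars``) contribute only through
      the added-sugar estimate.
    * Dairy ingredients are form-converted then multiplied by their
      category's milk-equivalent factor; dairy fats (butter) ride this
      route into the dairy group, while lard/tallow/palm oil are mapped to
      ``saturated_fats`` by the mapping table.
    """
    grams = {g: 0.0 for g in FOOD_GROUPS}
    energy = 0.0
    for code, amount in ingredients:
        ing = mapping.get(code)
        energy += amount * ing.kcal_per_g
        if ing.group == EXCLUDED:
            continue

        added = 0.0
        if ing.sugar_group is not None and ing.total_sugar_per_g > 0:
            added = estimate_added_sugars(
                amount, ing.total_sugar_per_g, ing.sugar_group, conversions.sugar
            )
            grams["added_sugars"] += added
        if ing.group == "added_sugars":
            continue

        effective = amount - added if conversions.subtract_added_sugar_from_source else amount
        raw = convert_form(code, effective, conversions.form)
        if ing.group == "dairy":
            grams["dairy"] += raw * conversions.dairy.factor(ing.dairy_category)
        else:
            grams[ing.group] += raw

    return GroupIntakeRow(
        child_id=day.child_id,
        day_index=day.day_index,
        weekday=day.weekday,
        age_years=day.age_years,
        grams=grams,
        energy_kcal=energy,
    )


def split_by_age_group(
    cohort: Cohort, boundary_years: float = 5.0
) -> tuple[Cohort, Cohort]:
    """Split record days into younger/older datasets by age at each day.

    Days are assigned by the child's decimal age on that day, using
    half-open intervals [3, boundary) and [boundary, 7); days outside
    [3, 7) are dropped.  A child with days on both sides appears in both
    cohorts (with only the respective days).
    """
    young_days: list[RecordDay] = []
    old_days: list[RecordDay] = []
    for day in cohort.days:
        if not 3.0 <= day.age_years < 7.0:
            continue
        (young_days if day.age_years < boundary_years else old_days).append(day)

    def sub(days: list[RecordDay]) -> Cohort:
        ids = {d.child_id for d in days}
        return Cohort(
            children={c: s for c, s in cohort.children.items() if c in ids},
            days=days,
        )

    return sub(young_days), sub(old_days)
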