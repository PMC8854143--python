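"""Measurement-convention conversions for reference-diet accounting.

The reference diet counts dairy foods in *milk equivalents* (grams of liquid
milk needed to produce one gram of the product), added sugars as a
food-group-specific fraction of each item's total sugar, and most other
foods in raw/dry form.  This module holds the three conversion tables and
the pure functions that apply them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DairyConversion",
    "SugarFormula",
    "FormFactor",
    "ConversionConfig",
    "to_milk_equivalents",
    "estimate_added_sugars",
    "convert_form",
    "DEFAULT_DAIRY_FACTORS",
    "DEFAULT_ADDED_FRACTIONS",
]

#: Milk-equivalent factors (g milk per g product), total-solids based.
DEFAULT_DAIRY_FACTORS: dict[str, float] = {
    "milk": 1.0,
    "sour_milk": 1.0,
    "yoghurt": 1.0,
    "cream": 2.7,
    "cheese": 5.0,
    "butter": 6.5,
}

#: Share of total sugar that is added, per sugar group.  Illustrative,
#: editable defaults: the fractions used in any given study come from its
#: own label/recipe review and ship as configuration.
DEFAULT_ADDED_FRACTIONS: dict[str, float] = {
    "sweets": 1.0,
    "sugar": 1.0,
    "sugary_drinks": 0.9,
    "sweetened_dairy": 0.6,
    "biscuits": 0.8,
    "unsweetened": 0.0,
}


class ConversionError(KeyError):
    """A category/group required by a conversion is missing from its table."""


@dataclass(frozen=True)
class DairyConversion:
    """Dairy category -> milk-equivalent factor (g milk per g product).

    The ``milk`` category must map to exactly 1.0; all factors are > 0.
    Fermented liquids (yoghurt, sour milk) default to 1.0 unless overridden.
    """

    factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DAIRY_FACTORS)
    )

    def __post_init__(self) -> None:
        for cat, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"milk-equivalent factor for {cat!r} must be > 0, got {f}")
        if "milk" in self.factors and self.factors["milk"] != 1.0:
            raise ValueError("factor for category 'milk' must be exactly 1.0")

    def factor(self, category: str) -> float:
        try:
            return self.factors[category]
        except KeyError:
            raise ConversionError(f"unknown dairy category {category!r}") from None


@dataclass(frozen=True)
class SugarFormula:
    """Added-sugar estimation tables.

    ``added_fraction`` maps a sugar group (e.g. ``biscuits``, ``yoghurts``)
    to the share f in [0, 1] of total sugar that is added; each food's total
    sugar content (g sugar per g food, in [0, 1]) travels with the food's
    mapping metadata and is passed to :func:`estimate_added_sugars`.
    """

    added_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADDED_FRACTIONS)
    )

    def __post_init__(self) -> None:
        for grp, f in self.added_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"added fraction for {grp!r} must be in [0, 1], got {f}")

    def fraction(self, sugar_group: str) -> float:
        try:
            return self.added_fraction[sugar_group]
        except KeyError:
            raise ConversionError(f"unknown sugar group {sugar_group!r}") from None


@dataclass(frozen=True)
class FormFactor:
    """Ingredient -> cooked/as-consumed to raw-or-dry conversion factor.

    Factors are g raw-or-dry per g as consumed (e.g. cooked pasta ~0.4 g dry
    per g cooked).  Ingredients without a configured factor pass through
    unchanged (identity fallback).
    """

    factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"form factor for {code!r} must be > 0, got {f}")

    def factor(self, ingredient_code: str) -> float:
        return self.factors.get(ingredient_code, 1.0)


@dataclass(frozen=True)
class ConversionConfig:
    """Bundle of the three conversion tables plus accounting flags.

    ``subtract_added_sugar_from_source``: when True, estimated added sugar
    is removed from the source food's mass before it contributes to its own
    food group; when False (default) the sugar mass is counted both in the
    source group and in added sugars.
    """

    dairy: DairyConversion = field(default_factory=DairyConversion)
    sugar: SugarFormula = field(default_factory=SugarFormula)
    form: FormFactor = field(default_factory=FormFactor)
    subtract_added_sugar_from_source: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConversionConfig":
        return cls(
            dairy=DairyConversion(dict(d.get("dairy_factors", DEFAULT_DAIRY_FACTORS))),
            sugar=SugarFormula(dict(d.get("added_fractions", DEFAULT_ADDED_FRACTIONS))),
            form=FormFactor(dict(d.get("form_factors", {}))),
            subtract_added_sugar_from_source=bool(
                d.get("subtract_added_sugar_from_source", False)
            ),
        )

    def to_dict(self) -> dict:
        return {
            "dairy_factors": dict(self.dairy.factors),
            "added_fractions": dict(self.sugar.added_fraction),
            "form_factors": dict(self.form.factors),
            "subtract_added_sugar_from_source": self.subtract_added_sugar_from_source,
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "ConversionConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def to_milk_equivalents(
    amounts: Iterable[tuple[str, float]], conv: DairyConversion
) -> float:
    """Total milk equivalents (g) of dairy products.

    Each (category, grams) pair contributes grams x factor; the sum is
    linear in its inputs.
    """
    return sum(amount * conv.factor(cat) for cat, amount in amounts)


def estimate_added_sugars(
    amount_g: float,
    total_sugar_per_g: float,
    sugar_group: str,
    formula: SugarFormula,
) -> float:
    """Estimated added sugar (g) in ``amount_g`` of a food.

    amount x total sugar content x added fraction of the food's sugar group.
    Never exceeds the food's total sugar mass.
    """
    if not 0.0 <= total_sugar_per_g <= 1.0:
        raise ValueError(f"total_sugar_per_g must be in [0, 1], got {total_sugar_per_g}")
    return amount_g * total_sugar_per_g * formula.fraction(sugar_group)


def convert_form(ingredient_code: str, amount_g: float, factors: FormFactor) -> float:
    """Convert an as-consumed amount to its raw/dry-form equivalent.

    Identity when no factor is configured for the ingredient.
    """
    return amount_g * factors.factor(ingredient_code)
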