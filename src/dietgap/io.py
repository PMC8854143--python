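"""Reading and writing the pipeline's delimited-text interfaces.

All inputs are UTF-8 CSV (or JSON for configuration): food records, the
children roster, the recipe database, the ingredient -> food-group mapping,
and the conversion configuration.  Loaders validate eagerly and report the
offending line number.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from .records import (
    Cohort,
    GroupMapping,
    MappedIngredient,
    Recipe,
    RecipeDB,
    RecordDay,
    WEEKDAYS,
)

__all__ = [
    "load_records",
    "load_recipes",
    "load_mapping",
    "write_records",
    "write_recipes",
    "write_mapping",
]

RECORD_COLUMNS = ["child_id", "day_index", "weekday", "age_years", "food_code", "amount_g"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def load_records(records_path: str | Path, children_path: str | Path) -> Cohort:
    """Load day-level food records plus the child roster into a Cohort.

    ``records_path``: CSV with columns child_id, day_index, weekday,
    age_years, food_code, amount_g (one row per consumed item).
    ``children_path``: CSV with columns child_id, sex.
    """
    rec = pd.read_csv(records_path, dtype={"child_id": str, "food_code": str})
    _require_columns(rec, RECORD_COLUMNS, records_path)
    kids = pd.read_csv(children_path, dtype={"child_id": str})
    _require_columns(kids, ["child_id", "sex"], children_path)

    children = dict(zip(kids["child_id"], kids["sex"]))
    if len(children) != len(kids):
        raise ValueError(f"{children_path}: duplicate child_id rows")

    grouped: dict[tuple[str, int], list] = defaultdict(list)
    meta: dict[tuple[str, int], tuple[str, float]] = {}
    for i, row in enumerate(rec.itertuples(index=False), start=2):
        try:
            key = (str(row.child_id), int(row.day_index))
            amount = float(row.amount_g)
            weekday = str(row.weekday)
            age = float(row.age_years)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{records_path}, line {i}: {exc}") from exc
        if weekday not in WEEKDAYS:
            raise ValueError(
                f"{records_path}, line {i}: weekday {weekday!r} not one of {WEEKDAYS}"
            )
        if amount < 0:
            raise ValueError(f"{records_path}, line {i}: negative amount {amount}")
        prev = meta.get(key)
        if prev is not None and prev != (weekday, age):
            raise ValueError(
                f"{records_path}, line {i}: inconsistent weekday/age for child "
                f"{key[0]} day {key[1]}"
            )
        meta[key] = (weekday, age)
        grouped[key].append((str(row.food_code), amount))

    days = [
        RecordDay(
            child_id=cid,
            day_index=didx,
            weekday=meta[(cid, didx)][0],
            age_years=meta[(cid, didx)][1],
            entries=tuple(entries),
        )
        for (cid, didx), entries in sorted(grouped.items())
    ]
    return Cohort(children=children, days=days)


def write_records(cohort: Cohort, records_path: str | Path, children_path: str | Path) -> None:
    rows = [
        (d.child_id, d.day_index, d.weekday, d.age_years, code, amount)
        for d in cohort.days
        for code, amount in d.entries
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(records_path, index=False)
    pd.DataFrame(
        sorted(cohort.children.items()), columns=["child_id", "sex"]
    ).to_csv(children_path, index=False)


def load_recipes(path: str | Path) -> RecipeDB:
    """Load a recipe database from CSV (product_code, ingredient_code, mass_share)."""
    df = pd.read_csv(path, dtype={"product_code": str, "ingredient_code": str})
    _require_columns(df, ["product_code", "ingredient_code", "mass_share"], path)
    components: dict[str, list] = defaultdict(list)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            share = float(row.mass_share)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
        components[str(row.product_code)].append((str(row.ingredient_code), share))
    try:
        return RecipeDB(
            Recipe(product_code=p, components=tuple(comps)) for p, comps in components.items()
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_recipes(db: RecipeDB, path: str | Path) -> None:
    rows = [
        (p, code, share)
        for p in db.product_codes()
        for code, share in db.get(p).components
    ]
    pd.DataFrame(rows, columns=["product_code", "ingredient_code", "mass_share"]).to_csv(
        path, index=False
    )


MAPPING_COLUMNS = [
    "ingredient_code",
    "group",
    "name",
    "dairy_category",
    "sugar_group",
    "total_sugar_per_g",
    "kcal_per_g",
    "is_representative",
]


def load_mapping(path: str | Path) -> GroupMapping:
    """Load the ingredient -> food-group mapping with conversion metadata."""
    df = pd.read_csv(path, dtype={"ingredient_code": str})
    _require_columns(df, ["ingredient_code", "group"], path)
    ingredients = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()

        def opt_str(key):
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else str(v)

        try:
            ingredients.append(
                MappedIngredient(
                    code=str(d["ingredient_code"]),
                    group=str(d["group"]),
                    name=opt_str("name") or "",
                    dairy_category=opt_str("dairy_category"),
                    sugar_group=opt_str("sugar_group"),
                    total_sugar_per_g=float(d.get("total_sugar_per_g", 0.0) or 0.0),
                    kcal_per_g=float(d.get("kcal_per_g", 0.0) or 0.0),
                    is_representative=bool(d.get("is_representative", False)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    try:
        return GroupMapping(ingredients)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_mapping(mapping: GroupMapping, path: str | Path) -> None:
    rows = []
    for code in sorted(mapping.codes()):
        ing = mapping.get(code)
        rows.append(
            (
                ing.code,
                ing.group,
                ing.name,
                ing.dairy_category or "",
                ing.sugar_group or "",
                ing.total_sugar_per_g,
                ing.kcal_per_g,
                ing.is_representative,
            )
        )
    pd.DataFrame(rows, columns=MAPPING_COLUMNS).to_csv(path, index=False)
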