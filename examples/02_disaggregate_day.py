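"""Disaggregate one record day into food-group grams.

A day's foods — including composite dishes — are expanded recursively to
base ingredients by recipe mass shares, then classified into reference-
diet groups with milk-equivalent, added-sugar and raw/dry conversions.
"""

from dietgap import RecordDay, classify_day, expand_to_ingredients
from dietgap.synthetic import build_food_library

recipes, mapping, conversions = build_food_library()

day = RecordDay(
    child_id="demo",
    day_index=1,
    weekday="Tue",
    age_years=4.2,
    entries=(
        ("oat_porridge", 200.0),   # recipe: 35% oat flakes, 65% milk
        ("cheese", 20.0),          # milk-equivalent factor 5.0
        ("flavoured_yoghurt", 150.0),  # carries added sugar (12% sugar, 60% added)
        ("squash_drink", 200.0),   # water (excluded) + sugar
        ("potato", 120.0),
    ),
)

ingredients = expand_to_ingredients(day, recipes, base_codes=mapping.codes())
print("base ingredients (g as consumed):")
for code, amount in ingredients:
    print(f"  {code:<20s} {amount:7.1f}")

row = classify_day(day, ingredients, mapping, conversions)
print("\nfood-group grams (dairy in milk equivalents):")
for group, grams in row.grams.items():
    if grams:
        print(f"  {group:<16s} {grams:7.1f}")
print(f"  energy           {row.energy_kcal:7.0f} kcal")

# The porridge splits into oats and milk; cheese enters dairy at 5x its
# mass; the drink's water is excluded while its sugar lands in
# added_sugars together with the yoghurt's estimated added sugar.
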