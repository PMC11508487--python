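# Default rule table: a WPRO-style nutrient profile model for marketing to
# children. Category structure follows the WHO regional models (category-level
# prohibitions for confectionery/energy drinks/etc., per-nutrient limits and
# ingredient triggers elsewhere).
#
# BEST-EFFORT TRANSCRIPTION: the numeric limits below are plausible encodings,
# not an authoritative reproduction of the published WHO Western Pacific model.
# Verify every limit against the official publication before any policy use.
# Nothing in the package's validated behaviour depends on these specific
# numbers; the engine is entirely rule-table-driven.
table_id: wpro-default
version: "2016-draft-transcription"
rules:
  - category_code: chocolate_confectionery
    label: Chocolate and sugar confectionery, energy bars, sweet toppings and desserts
    mode: always_prohibited
  - category_code: cakes_sweet_biscuits
    label: Cakes, sweet biscuits and pastries, other sweet bakery wares
    mode: always_prohibited
  - category_code: ice_cream
    label: Ice cream and edible ices
    mode: always_prohibited
  - category_code: energy_drinks
    label: Energy drinks
    mode: always_prohibited
  - category_code: juices
    label: Fruit and vegetable juices
    mode: always_prohibited
  - category_code: savoury_snacks
    label: Savoury snacks
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 10, basis: per_100g}
      - {nutrient: total_sugars_g, limit: 10, basis: per_100g}
      - {nutrient: sodium_mg, limit: 100, basis: per_100g}
  - category_code: breakfast_cereals
    label: Breakfast cereals
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 10, basis: per_100g}
      - {nutrient: total_sugars_g, limit: 15, basis: per_100g}
      - {nutrient: sodium_mg, limit: 400, basis: per_100g}
  - category_code: yoghurts
    label: Yoghurts, sour milk and cream
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 2.5, basis: per_100g}
      - {nutrient: sat_fat_g, limit: 2.0, basis: per_100g}
      - {nutrient: total_sugars_g, limit: 10, basis: per_100g}
      - {nutrient: sodium_mg, limit: 100, basis: per_100g}
  - category_code: cheese
    label: Cheese
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 20, basis: per_100g}
      - {nutrient: sat_fat_g, limit: 10, basis: per_100g}
      - {nutrient: sodium_mg, limit: 520, basis: per_100g}
  - category_code: ready_meals
    label: Ready-made and convenience foods, composite dishes
    mode: threshold_based
    criteria:
      - {nutrient: energy_kj, limit: 941, basis: per_100g}
      - {nutrient: total_fat_g, limit: 10, basis: per_100g}
      - {nutrient: sat_fat_g, limit: 4, basis: per_100g}
      - {nutrient: total_sugars_g, limit: 10, basis: per_100g}
      - {nutrient: sodium_mg, limit: 400, basis: per_100g}
  - category_code: processed_meat_fish
    label: Processed meat, poultry, fish and analogues
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 20, basis: per_100g}
      - {nutrient: sodium_mg, limit: 680, basis: per_100g}
  - category_code: bread_bakery
    label: Bread and ordinary bakery wares
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 10, basis: per_100g}
      - {nutrient: total_sugars_g, limit: 10, basis: per_100g}
      - {nutrient: sodium_mg, limit: 450, basis: per_100g}
  - category_code: fats_oils
    label: Butter, margarine, other fats and oils
    mode: threshold_based
    criteria:
      - {nutrient: sat_fat_g, limit: 20, basis: per_100g}
      - {nutrient: sodium_mg, limit: 520, basis: per_100g}
  - category_code: sauces_dressings
    label: Sauces, dips and dressings
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 10, basis: per_100g}
      - {nutrient: total_sugars_g, limit: 10, basis: per_100g}
      - {nutrient: sodium_mg, limit: 400, basis: per_100g}
  - category_code: milk_drinks
    label: Milk and dairy-based drinks, plant-based milks
    mode: threshold_based
    criteria:
      - {nutrient: total_fat_g, limit: 2.5, basis: per_100mL}
    trigger_flags: [added_sugar_prohibited, non_sugar_sweetener_prohibited]
  - category_code: other_beverages
    label: Waters and other beverages
    mode: threshold_based
    criteria:
      - {nutrient: energy_kj, limit: 20, basis: per_100mL}
    trigger_flags: [added_sugar_prohibited, non_sugar_sweetener_prohibited]
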