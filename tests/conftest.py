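from __future__ import annotations

import numpy as np
import pytest

from brandscreen.npm_engine import (
    NUTRIENT_FIELDS,
    TRIGGER_FLAG_FIELDS,
    NutrientVector,
    ProductRecord,
    RuleTable,
    load_rule_table,
)

SIMPLE_RULES_CONFIG = {
    "table_id": "test-simple",
    "version": "1",
    "rules": [
        {
            "category_code": "chocolate_confectionery",
            "label": "chocolate and confectionery",
            "mode": "always_prohibited",
        },
        {
            "category_code": "cheese",
            "mode": "threshold_based",
            "criteria": [
                {"nutrient": "sat_fat_g", "limit": 10.0, "basis": "per_100g"},
                {"nutrient": "sodium_mg", "limit": 500.0, "basis": "per_100g"},
            ],
        },
        {
            "category_code": "milk",
            "mode": "threshold_based",
            "criteria": [
                {"nutrient": "total_fat_g", "limit": 2.5, "basis": "per_100mL"}
            ],
            "trigger_flags": ["added_sugar_prohibited"],
        },
    ],
}


@pytest.fixture()
def simple_rules() -> RuleTable:
    return load_rule_table(SIMPLE_RULES_CONFIG)


def make_product(
    product_id: str = "p1",
    brand_id: str = "b1",
    npm_category: str = "cheese",
    nutrients: dict | None = None,
    imputed_status: str | None = None,
) -> ProductRecord:
    """Product factory; ``nutrients=None`` means no nutrient data at all."""
    vector = None if nutrients is None else NutrientVector(**nutrients)
    return ProductRecord(
        product_id=product_id,
        brand_id=brand_id,
        name=product_id,
        npm_category=npm_category,
        nutrients=vector,
        imputed_status=imputed_status,
    )


def random_product(
    rng: np.random.Generator, rules: RuleTable, product_id: str = "p"
) -> ProductRecord:
    """A random (possibly partial, possibly imputed) product for oracle checks.

    The basis always matches the chosen rule's criteria so the draw stays in
    the engine's valid input domain.
    """
    rule = rules.rules[int(rng.integers(len(rules.rules)))]
    if rng.random() < 0.05:
        return make_product(
            product_id,
            npm_category=rule.category_code,
            imputed_status=str(rng.choice(["permitted", "not_permitted"])),
        )
    if rng.random() < 0.1:
        return make_product(product_id, npm_category=rule.category_code)

    basis = rule.criteria[0].basis if rule.criteria else "per_100g"
    fields: dict = {"basis": basis}
    limits = {c.nutrient: c.limit for c in rule.criteria}
    for nutrient in NUTRIENT_FIELDS:
        if rng.random() < 0.8:
            scale = limits.get(nutrient, 100.0)
            fields[nutrient] = float(np.round(rng.uniform(0, 2.0 * scale), 3))
    for flag_field in TRIGGER_FLAG_FIELDS.values():
        draw = rng.random()
        if draw < 1 / 3:
            fields[flag_field] = bool(draw < 1 / 6)
    return make_product(product_id, npm_category=rule.category_code, nutrients=fields)
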