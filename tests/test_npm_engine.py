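from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brandscreen.errors import (
    BasisMismatchError,
    RuleTableError,
    UnknownCategoryError,
)
from brandscreen.io_reporting import load_default_rules
from brandscreen.npm_engine import (
    NutrientVector,
    classify_product,
    classify_products,
    load_rule_table,
)
from brandscreen.synthetic_data import generate_rule_table

from .conftest import SIMPLE_RULES_CONFIG, make_product, random_product
from .oracle import brute_force_status


class TestLoadRuleTable:
    def test_minimal_table(self):
        table = load_rule_table(
            {
                "table_id": "mini",
                "rules": [
                    {"category_code": "confectionery", "mode": "always_prohibited"}
                ],
            }
        )
        assert len(table.rules) == 1
        assert table.rule_for("confectionery").mode == "always_prohibited"

    def test_shipped_default_prohibits_confectionery_and_energy_drinks(self):
        table = load_default_rules()
        prohibited = {
            r.category_code for r in table.rules if r.mode == "always_prohibited"
        }
        assert len(prohibited) >= 2
        assert "chocolate_confectionery" in prohibited
        assert "energy_drinks" in prohibited

    def test_duplicate_category_codes_rejected(self):
        config = {
            "table_id": "dup",
            "rules": [
                {"category_code": "c", "mode": "always_prohibited"},
                {"category_code": "c", "mode": "always_prohibited"},
            ],
        }
        with pytest.raises(RuleTableError, match="duplicate"):
            load_rule_table(config)

    def test_unknown_nutrient_rejected(self):
        config = {
            "table_id": "bad",
            "rules": [
                {
                    "category_code": "c",
                    "mode": "threshold_based",
                    "criteria": [
                        {"nutrient": "fibre_g", "limit": 1.0, "basis": "per_100g"}
                    ],
                }
            ],
        }
        with pytest.raises(RuleTableError, match="fibre_g"):
            load_rule_table(config)

    def test_prohibited_rule_with_criteria_rejected(self):
        config = {
            "table_id": "bad",
            "rules": [
                {
                    "category_code": "c",
                    "mode": "always_prohibited",
                    "criteria": [
                        {"nutrient": "sodium_mg", "limit": 1.0, "basis": "per_100g"}
                    ],
                }
            ],
        }
        with pytest.raises(RuleTableError, match="'c'"):
            load_rule_table(config)

    def test_yaml_string_and_roundtrip(self):
        import yaml

        table = load_rule_table(yaml.safe_dump(SIMPLE_RULES_CONFIG))
        assert table.category_codes == ("chocolate_confectionery", "cheese", "milk")


class TestClassifyProduct:
    def test_prohibited_category_ignores_nutrients(self, simple_rules):
        product = make_product(
            npm_category="chocolate_confectionery",
            nutrients={"basis": "per_100g", "total_sugars_g": 0.0},
        )
        result = classify_product(product, simple_rules)
        assert result.status == "not_permitted"
        assert result.reason == "category_prohibition"

    def test_missing_nutrient_data_is_unclassifiable(self, simple_rules):
        result = classify_product(make_product(nutrients=None), simple_rules)
        assert result.status == "unclassifiable"
        assert result.reason == "missing_data"

    def test_saturated_fat_over_limit_fails_with_audit_trail(self, simple_rules):
        product = make_product(
            nutrients={"basis": "per_100g", "sat_fat_g": 22.0, "sodium_mg": 400.0}
        )
        result = classify_product(product, simple_rules)
        assert result.status == "not_permitted"
        assert result.reason == "nutrient_limit"
        assert [(f.criterion, f.observed, f.limit) for f in result.failed_criteria] == [
            ("sat_fat_g", 22.0, 10.0)
        ]

    def test_added_sugar_trigger_fails_milk(self, simple_rules):
        product = make_product(
            npm_category="milk",
            nutrients={
                "basis": "per_100mL",
                "total_fat_g": 1.5,
                "added_sugar_present": True,
            },
        )
        result = classify_product(product, simple_rules)
        assert result.status == "not_permitted"
        assert result.reason == "trigger_flag"
        assert result.fired_flags == ("added_sugar_prohibited",)

    def test_unknown_required_flag_is_unclassifiable(self, simple_rules):
        product = make_product(
            npm_category="milk",
            nutrients={"basis": "per_100mL", "total_fat_g": 1.5},
        )
        result = classify_product(product, simple_rules)
        assert result.status == "unclassifiable"
        assert result.reason == "missing_data"

    def test_all_criteria_satisfied_is_permitted(self, simple_rules):
        product = make_product(
            nutrients={"basis": "per_100g", "sat_fat_g": 9.9, "sodium_mg": 499.0}
        )
        result = classify_product(product, simple_rules)
        assert result.status == "permitted"
        assert result.reason == "passed"
        assert result.failed_criteria == ()

    def test_value_at_limit_passes(self, simple_rules):
        product = make_product(
            nutrients={"basis": "per_100g", "sat_fat_g": 10.0, "sodium_mg": 500.0}
        )
        assert classify_product(product, simple_rules).status == "permitted"

    def test_imputed_status_short_circuits(self, simple_rules):
        product = make_product(imputed_status="not_permitted", nutrients=None)
        result = classify_product(product, simple_rules)
        assert result.status == "not_permitted"
        assert result.reason == "imputed"

    def test_missing_required_nutrient_is_unclassifiable(self, simple_rules):
        # sodium present and failing, but sat fat unknown: still unclassifiable
        product = make_product(
            nutrients={"basis": "per_100g", "sodium_mg": 900.0}
        )
        result = classify_product(product, simple_rules)
        assert result.status == "unclassifiable"

    def test_unresolvable_category_names_product(self, simple_rules):
        product = make_product(product_id="mystery", npm_category="nope")
        with pytest.raises(UnknownCategoryError, match="mystery"):
            classify_product(product, simple_rules)

    def test_basis_mismatch_is_an_error(self, simple_rules):
        product = make_product(
            nutrients={"basis": "per_100mL", "sat_fat_g": 1.0, "sodium_mg": 1.0}
        )
        with pytest.raises(BasisMismatchError):
            classify_product(product, simple_rules)

    def test_negative_nutrient_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            NutrientVector(basis="per_100g", sodium_mg=-1.0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    sat_fat=st.floats(0.0, 9.99),
    sodium=st.floats(0.0, 499.0),
    bump=st.floats(0.0, 1000.0),
    target=st.sampled_from(["sat_fat_g", "sodium_mg"]),
)
def test_increasing_a_criterion_nutrient_never_rescues_a_product(
    sat_fat, sodium, bump, target
):
    """Monotonicity: raising any limited nutrient can only lose permission."""
    rules = load_rule_table(SIMPLE_RULES_CONFIG)
    base = {"basis": "per_100g", "sat_fat_g": sat_fat, "sodium_mg": sodium}
    before = classify_product(make_product(nutrients=base), rules)
    bumped = dict(base, **{target: base[target] + bump})
    after = classify_product(make_product(nutrients=bumped), rules)
    assert not (before.status == "not_permitted" and after.status == "permitted")
    if before.status == "permitted":
        assert after.status in ("permitted", "not_permitted")


def test_engine_matches_brute_force_oracle_on_random_inputs():
    """Criterion-by-criterion independent re-evaluation agrees everywhere."""
    rng = np.random.default_rng(20240)
    for table_seed in range(30):
        rules = generate_rule_table(
            n_categories=int(rng.integers(1, 8)),
            prohibited_fraction=float(rng.uniform(0, 1)),
            seed=int(rng.integers(2**31)),
        )
        for j in range(10):
            product = random_product(rng, rules, product_id=f"t{table_seed}p{j}")
            result = classify_product(product, rules)
            assert result.status == brute_force_status(product, rules)


def test_determinism_and_exhaustiveness(simple_rules):
    rng = np.random.default_rng(7)
    products = [random_product(rng, simple_rules, f"p{i}") for i in range(50)]
    first = classify_products(products, simple_rules)
    second = classify_products(products, simple_rules)
    assert first == second
    counts = {"permitted": 0, "not_permitted": 0, "unclassifiable": 0}
    for r in first:
        counts[r.status] += 1
    assert sum(counts.values()) == len(products)
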