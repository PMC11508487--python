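"""Independent brute-force oracle for the rule engine.

Re-derives every decision from first principles (criterion-by-criterion
re-check, naive recounting), sharing no code path with the engine under test.
"""

from __future__ import annotations

from brandscreen.npm_engine import ProductRecord, RuleTable, TRIGGER_FLAG_FIELDS


def brute_force_status(product: ProductRecord, rules: RuleTable) -> str:
    """Naively re-evaluate one product; returns the expected status string."""
    rule = next(r for r in rules.rules if r.category_code == product.npm_category)

    if product.imputed_status is not None:
        return product.imputed_status
    if rule.mode == "always_prohibited":
        return "not_permitted"
    if product.nutrients is None:
        return "unclassifiable"

    observed = {
        c.nutrient: getattr(product.nutrients, c.nutrient) for c in rule.criteria
    }
    if any(v is None for v in observed.values()):
        return "unclassifiable"
    if any(observed[c.nutrient] > c.limit for c in rule.criteria):
        return "not_permitted"

    flags = {
        flag: getattr(product.nutrients, TRIGGER_FLAG_FIELDS[flag])
        for flag in rule.trigger_flags
    }
    if any(v is True for v in flags.values()):
        return "not_permitted"
    if any(v is None for v in flags.values()):
        return "unclassifiable"
    return "permitted"


def naive_brand_percent(statuses: list[str]) -> float | None:
    """Percent permitted over classified products, by direct recount."""
    classified = [s for s in statuses if s != "unclassifiable"]
    if not classified:
        return None
    return 100.0 * classified.count("permitted") / len(classified)
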