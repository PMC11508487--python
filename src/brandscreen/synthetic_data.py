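"""Synthetic product portfolios with known ground truth.

Real nutrient-composition databases of branded products are proprietary, so
every pipeline stage here is exercised on generated portfolios instead: brands
with a controllable *true* fraction of permitted products, nutrient vectors
placed deterministically below or above their category's limits, and a
controllable missing-data rate applied *after* the true labels are fixed (so
ground truth exists even for products the pipeline must call unclassifiable).

Defaults emulate the study setting the package was built around: 20 packaged
food brands, 20 beverage brands and 12 fast-food brands, with per-sector true
permitted fractions of 37% / 7% / 20% and missing-nutrient rates of ~1% / 0% /
58%.

Randomness comes from a single integer seed. Draw order is fixed and
documented in :func:`generate_portfolio` so results are stable across
releases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .brand_classifier import Sector
from .errors import SyntheticSpecError
from .npm_engine import CategoryRule, Criterion, RuleTable

__all__ = [
    "SECTORS",
    "SyntheticSpec",
    "SyntheticPortfolio",
    "generate_rule_table",
    "generate_portfolio",
]

SECTORS: tuple[Sector, ...] = ("packaged_food", "beverage", "fast_food")

# Plausible per-100g/100mL sampling ranges for random rule limits.
_LIMIT_RANGES: dict[str, tuple[float, float]] = {
    "energy_kj": (400.0, 2000.0),
    "total_fat_g": (3.0, 25.0),
    "sat_fat_g": (1.0, 12.0),
    "total_sugars_g": (4.0, 25.0),
    "sodium_mg": (80.0, 700.0),
    "protein_g": (2.0, 15.0),
}

_FLAG_COLUMNS = {"added_sugar_prohibited": "added_sugar",
                 "non_sugar_sweetener_prohibited": "non_sugar_sweetener"}


class SyntheticSpec(BaseModel):
    """Parameters of a synthetic portfolio.

    ``true_permitted_fraction`` and ``missing_rate`` may be a single float
    (applied to every sector) or a per-sector mapping.
    """

    model_config = ConfigDict(frozen=True)

    n_brands: dict[Sector, int] = {
        "packaged_food": 20,
        "beverage": 20,
        "fast_food": 12,
    }
    products_per_brand: tuple[int, int] = (5, 300)
    true_permitted_fraction: Union[float, dict[Sector, float]] = {
        "packaged_food": 0.37,
        "beverage": 0.07,
        "fast_food": 0.20,
    }
    missing_rate: Union[float, dict[Sector, float]] = {
        "packaged_food": 14 / 1564,
        "beverage": 0.0,
        "fast_food": 0.58,
    }
    prohibited_category_fraction: float = 0.25
    seed: int = 0

    @field_validator("n_brands")
    @classmethod
    def _brands_non_negative(cls, v):
        if any(n < 0 for n in v.values()):
            raise ValueError("n_brands values must be >= 0")
        return v

    @field_validator("products_per_brand")
    @classmethod
    def _valid_range(cls, v):
        lo, hi = v
        if lo < 1 or hi < lo:
            raise ValueError(f"products_per_brand must satisfy 1 <= lo <= hi, got {v}")
        return v

    @field_validator("true_permitted_fraction", "missing_rate",
                     "prohibited_category_fraction")
    @classmethod
    def _unit_interval(cls, v):
        values = v.values() if isinstance(v, dict) else [v]
        if any(not 0.0 <= x <= 1.0 for x in values):
            raise ValueError(f"fractions must lie in [0, 1], got {v}")
        return v

    def permitted_fraction_for(self, sector: Sector) -> float:
        v = self.true_permitted_fraction
        return v[sector] if isinstance(v, dict) else v

    def missing_rate_for(self, sector: Sector) -> float:
        v = self.missing_rate
        return v[sector] if isinstance(v, dict) else v


@dataclass(frozen=True)
class SyntheticPortfolio:
    """Generated product table plus everything needed to audit it."""

    products: pd.DataFrame  # documented product column dictionary
    brands: pd.DataFrame    # brand_id, sector, true_permitted_fraction, n_products
    truth: pd.DataFrame     # product_id, brand_id, sector, true_status, blanked
    rules: RuleTable


def generate_rule_table(
    n_categories: int,
    prohibited_fraction: float,
    seed: int,
) -> RuleTable:
    """Random but valid rule table mixing prohibitions and nutrient limits.

    Each threshold-based category draws 1-3 criteria (one shared basis) with
    limits uniform over plausible per-100g/100mL ranges, plus an ingredient
    trigger flag with probability 0.25. If ``prohibited_fraction < 1`` at
    least one threshold-based category is guaranteed.
    """
    if n_categories < 1:
        raise SyntheticSpecError("n_categories must be >= 1")
    if not 0.0 <= prohibited_fraction <= 1.0:
        raise SyntheticSpecError("prohibited_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    modes = rng.random(n_categories) < prohibited_fraction
    if prohibited_fraction < 1.0 and modes.all():
        modes[-1] = False
    rules = []
    for i, prohibited in enumerate(modes):
        code = f"cat{i:02d}"
        if prohibited:
            rules.append(
                CategoryRule(
                    category_code=code,
                    label=f"synthetic prohibited category {i}",
                    mode="always_prohibited",
                )
            )
            continue
        basis = str(rng.choice(["per_100g", "per_100mL"]))
        n_crit = int(rng.integers(1, 4))
        nutrients = rng.choice(list(_LIMIT_RANGES), size=n_crit, replace=False)
        criteria = tuple(
            Criterion(
                nutrient=str(nut),
                limit=float(np.round(rng.uniform(*_LIMIT_RANGES[str(nut)]), 1)),
                basis=basis,
            )
            for nut in nutrients
        )
        flags = frozenset()
        if rng.random() < 0.25:
            flags = frozenset({str(rng.choice(sorted(_FLAG_COLUMNS)))})
        rules.append(
            CategoryRule(
                category_code=code,
                label=f"synthetic threshold category {i}",
                mode="threshold_based",
                criteria=criteria,
                trigger_flags=flags,
            )
        )
    return RuleTable(
        table_id=f"synthetic-{seed}", version="1", rules=tuple(rules)
    )


def generate_portfolio(
    spec: SyntheticSpec, rules: Optional[RuleTable] = None
) -> SyntheticPortfolio:
    """Generate a product table whose true labels are known by construction.

    Permitted products get every criterion nutrient strictly below its limit
    (10-90% of it) and required trigger flags set false; not-permitted
    products either land in an always-prohibited category (with probability
    ``prohibited_category_fraction``) or violate exactly one criterion
    (110-200% of its limit) / fire one trigger flag. Nutrients are blanked at
    ``missing_rate`` only after labels are fixed.

    Draw order (one ``numpy`` generator seeded with ``spec.seed``): sectors in
    the fixed order packaged_food, beverage, fast_food; per brand, its product
    count; per product, the label coin, the category choice and the nutrient
    values; finally one missingness pass over all products in row order. The
    default rule table, when none is supplied, uses ``spec.seed`` with its own
    generator.

    Raises
    ------
    SyntheticSpecError
        If a sector needs permitted products but the rule table has no
        threshold-based (i.e. satisfiable) category.
    """
    if rules is None:
        rules = generate_rule_table(
            n_categories=12,
            prohibited_fraction=spec.prohibited_category_fraction,
            seed=spec.seed,
        )
    threshold_rules = [r for r in rules.rules if r.mode == "threshold_based"]
    prohibited_rules = [r for r in rules.rules if r.mode == "always_prohibited"]
    for sector in SECTORS:
        if (
            spec.n_brands.get(sector, 0) > 0
            and spec.permitted_fraction_for(sector) > 0.0
            and not threshold_rules
        ):
            raise SyntheticSpecError(
                f"sector {sector!r} requires permitted products but rule table "
                f"{rules.table_id!r} has no threshold-based category"
            )

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.products_per_brand
    product_rows: list[dict] = []
    truth_rows: list[dict] = []
    brand_rows: list[dict] = []

    for sector in SECTORS:
        frac = spec.permitted_fraction_for(sector)
        for b in range(spec.n_brands.get(sector, 0)):
            brand_id = f"{sector}_brand_{b:03d}"
            n_products = int(rng.integers(lo, hi + 1))
            brand_rows.append(
                {
                    "brand_id": brand_id,
                    "sector": sector,
                    "true_permitted_fraction": frac,
                    "n_products": n_products,
                }
            )
            for p in range(n_products):
                product_id = f"{brand_id}_p{p:04d}"
                permitted = bool(rng.random() < frac)
                row = _draw_product(
                    rng,
                    permitted,
                    threshold_rules,
                    prohibited_rules,
                    spec.prohibited_category_fraction,
                )
                row.update(
                    product_id=product_id,
                    brand_id=brand_id,
                    name=f"synthetic product {p}",
                )
                product_rows.append(row)
                truth_rows.append(
                    {
                        "product_id": product_id,
                        "brand_id": brand_id,
                        "sector": sector,
                        "true_status": "permitted" if permitted else "not_permitted",
                    }
                )

    from .io_reporting import PRODUCT_COLUMNS  # late import avoids a cycle

    products = pd.DataFrame(product_rows, columns=list(PRODUCT_COLUMNS))
    truth = pd.DataFrame(
        truth_rows, columns=["product_id", "brand_id", "sector", "true_status"]
    )
    brands = pd.DataFrame(
        brand_rows,
        columns=["brand_id", "sector", "true_permitted_fraction", "n_products"],
    )

    # The product table is a string table (its on-disk form); blank cells mean
    # missing. Format numerics before the missingness pass.
    blank_cols = [
        "basis", "energy_kj", "total_fat_g", "sat_fat_g", "total_sugars_g",
        "sodium_mg", "protein_g", "added_sugar", "non_sugar_sweetener",
    ]
    for col in ("energy_kj", "total_fat_g", "sat_fat_g", "total_sugars_g",
                "sodium_mg", "protein_g"):
        products[col] = products[col].map(lambda v: f"{v:g}")
    sector_of = truth["sector"].to_numpy()
    draws = rng.random(len(products))
    rates = np.array([spec.missing_rate_for(s) for s in sector_of])
    blanked = draws < rates
    products.loc[blanked, blank_cols] = ""
    truth["blanked"] = blanked

    return SyntheticPortfolio(
        products=products, brands=brands, truth=truth, rules=rules
    )


def _draw_product(
    rng: np.random.Generator,
    permitted: bool,
    threshold_rules: list[CategoryRule],
    prohibited_rules: list[CategoryRule],
    prohibited_category_fraction: float,
) -> dict:
    """Category + nutrient cells for one product with the requested label."""
    if not permitted and prohibited_rules and (
        not threshold_rules or rng.random() < prohibited_category_fraction
    ):
        rule = prohibited_rules[int(rng.integers(len(prohibited_rules)))]
        row = _background_nutrients(rng, str(rng.choice(["per_100g", "per_100mL"])))
        row["npm_category"] = rule.category_code
        return row

    rule = threshold_rules[int(rng.integers(len(threshold_rules)))]
    basis = rule.criteria[0].basis if rule.criteria else str(
        rng.choice(["per_100g", "per_100mL"])
    )
    row = _background_nutrients(rng, basis)
    row["npm_category"] = rule.category_code
    for criterion in rule.criteria:
        row[criterion.nutrient] = float(
            np.round(criterion.limit * rng.uniform(0.1, 0.9), 2)
        )
    for flag in sorted(rule.trigger_flags):
        row[_FLAG_COLUMNS[flag]] = "false"
    if not permitted:
        if rule.criteria:
            victim = rule.criteria[int(rng.integers(len(rule.criteria)))]
            row[victim.nutrient] = float(
                np.round(victim.limit * rng.uniform(1.1, 2.0) + 0.01, 2)
            )
        else:  # flag-only rule: fire one trigger
            flag = sorted(rule.trigger_flags)[int(rng.integers(len(rule.trigger_flags)))]
            row[_FLAG_COLUMNS[flag]] = "true"
    return row


def _background_nutrients(rng: np.random.Generator, basis: str) -> dict:
    """Fill every nutrient field with a plausible (unchecked) value."""
    row = {"basis": basis, "imputed_status": "",
           "added_sugar": "", "non_sugar_sweetener": ""}
    for nutrient, (lo, hi) in _LIMIT_RANGES.items():
        row[nutrient] = float(np.round(rng.uniform(0.0, hi), 2))
    return row
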