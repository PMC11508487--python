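"""Nutrient-profile-model (NPM) rule engine.

Classifies a single product as ``permitted`` / ``not_permitted`` /
``unclassifiable`` for marketing to children under a data-driven rule table.
An NPM here is a set of category rules: a category is either *always
prohibited* (e.g. confectionery, energy drinks) or *threshold based*, in which
case the product must satisfy every per-nutrient limit (``observed <= limit``)
and must not fire any ingredient trigger (added sugar, non-sugar sweeteners).

The engine is deliberately decoupled from any one published model: the rules
are config data (see :func:`load_rule_table` and the shipped
``wpro_default.yaml``), so the same machinery can run the WHO Western Pacific
model, the WHO Europe model, or a synthetic table with known ground truth.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import BasisMismatchError, RuleTableError, UnknownCategoryError

__all__ = [
    "NUTRIENT_FIELDS",
    "TRIGGER_FLAG_FIELDS",
    "Basis",
    "NutrientVector",
    "ProductRecord",
    "Criterion",
    "CategoryRule",
    "RuleTable",
    "FailedCriterion",
    "ClassificationResult",
    "load_rule_table",
    "classify_product",
]

Basis = Literal["per_100g", "per_100mL"]
Status = Literal["permitted", "not_permitted", "unclassifiable"]
Reason = Literal[
    "category_prohibition",
    "nutrient_limit",
    "trigger_flag",
    "imputed",
    "missing_data",
    "passed",
]

#: Numeric nutrient fields a criterion may reference (per reference amount).
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kj",
    "total_fat_g",
    "sat_fat_g",
    "total_sugars_g",
    "sodium_mg",
    "protein_g",
)

#: Maps a rule trigger flag to the product field it inspects.
TRIGGER_FLAG_FIELDS: dict[str, str] = {
    "added_sugar_prohibited": "added_sugar_present",
    "non_sugar_sweetener_prohibited": "non_sugar_sweetener_present",
}


class NutrientVector(BaseModel):
    """Nutrient composition of one product, per 100 g or per 100 mL.

    Optional fields that are absent mean *unknown*, never zero: food
    composition databases frequently lack values, and a missing value must
    make a product unclassifiable rather than silently pass a limit.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    basis: Basis
    energy_kj: Optional[float] = None
    total_fat_g: Optional[float] = None
    sat_fat_g: Optional[float] = None
    total_sugars_g: Optional[float] = None
    sodium_mg: Optional[float] = None
    protein_g: Optional[float] = None
    added_sugar_present: Optional[bool] = None
    non_sugar_sweetener_present: Optional[bool] = None

    @field_validator(*NUTRIENT_FIELDS)
    @classmethod
    def _non_negative(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError(f"nutrient values must be >= 0, got {v}")
        return v


class ProductRecord(BaseModel):
    """One product: brand link, NPM category, nutrient vector, overrides.

    ``imputed_status`` is a manual per-product override that short-circuits the
    engine (used e.g. when a product class is known to fail the model even
    though its nutrient data is unavailable).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    product_id: str
    brand_id: str
    name: str = ""
    npm_category: str
    nutrients: Optional[NutrientVector] = None
    imputed_status: Optional[Literal["permitted", "not_permitted"]] = None


class Criterion(BaseModel):
    """One per-nutrient limit: passes when ``observed <= limit``."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    nutrient: str
    comparator: Literal["le"] = "le"
    limit: float
    basis: Basis

    @field_validator("nutrient")
    @classmethod
    def _known_nutrient(cls, v: str) -> str:
        if v not in NUTRIENT_FIELDS:
            raise ValueError(
                f"unknown nutrient {v!r}; expected one of {sorted(NUTRIENT_FIELDS)}"
            )
        return v


class CategoryRule(BaseModel):
    """The rule for one NPM category.

    ``always_prohibited`` categories (confectionery, energy drinks, ...) take
    no criteria: membership alone decides. ``threshold_based`` categories need
    at least one criterion or trigger flag.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    category_code: str
    label: str = ""
    mode: Literal["always_prohibited", "threshold_based"]
    criteria: tuple[Criterion, ...] = ()
    trigger_flags: frozenset[str] = frozenset()

    @field_validator("trigger_flags")
    @classmethod
    def _known_flags(cls, v: frozenset[str]) -> frozenset[str]:
        unknown = v - set(TRIGGER_FLAG_FIELDS)
        if unknown:
            raise ValueError(
                f"unknown trigger flags {sorted(unknown)}; "
                f"expected subset of {sorted(TRIGGER_FLAG_FIELDS)}"
            )
        return v

    @model_validator(mode="after")
    def _mode_consistent(self) -> "CategoryRule":
        if self.mode == "always_prohibited" and (self.criteria or self.trigger_flags):
            raise ValueError(
                f"rule {self.category_code!r}: always_prohibited rules must have "
                "no criteria and no trigger flags"
            )
        if self.mode == "threshold_based" and not (self.criteria or self.trigger_flags):
            raise ValueError(
                f"rule {self.category_code!r}: threshold_based rules need at "
                "least one criterion or trigger flag"
            )
        return self


class RuleTable(BaseModel):
    """A complete NPM as data: a non-empty set of uniquely coded rules."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    table_id: str
    version: str = ""
    rules: tuple[CategoryRule, ...]

    @model_validator(mode="after")
    def _codes_unique(self) -> "RuleTable":
        if not self.rules:
            raise ValueError("rule table must contain at least one rule")
        seen: set[str] = set()
        for rule in self.rules:
            if rule.category_code in seen:
                raise ValueError(f"duplicate category code {rule.category_code!r}")
            seen.add(rule.category_code)
        return self

    def rule_for(self, category_code: str) -> CategoryRule:
        for rule in self.rules:
            if rule.category_code == category_code:
                return rule
        raise UnknownCategoryError(
            f"category {category_code!r} not in rule table {self.table_id!r}"
        )

    @property
    def category_codes(self) -> tuple[str, ...]:
        return tuple(r.category_code for r in self.rules)


class FailedCriterion(BaseModel):
    """Audit record for one violated limit."""

    model_config = ConfigDict(frozen=True)

    criterion: str
    observed: float
    limit: float


class ClassificationResult(BaseModel):
    """Per-product decision with its audit trail.

    Exactly one ``reason`` accompanies each status; a permitted product never
    carries failed criteria.
    """

    model_config = ConfigDict(frozen=True)

    product_id: str
    status: Status
    reason: Reason
    failed_criteria: tuple[FailedCriterion, ...] = ()
    fired_flags: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _consistent(self) -> "ClassificationResult":
        if self.status == "permitted" and (self.failed_criteria or self.fired_flags):
            raise ValueError("permitted results must carry no failed criteria")
        if self.status == "not_permitted" and self.reason not in (
            "category_prohibition",
            "nutrient_limit",
            "trigger_flag",
            "imputed",
        ):
            raise ValueError(f"invalid reason {self.reason!r} for not_permitted")
        return self


def load_rule_table(config_source) -> RuleTable:
    """Load and validate a rule table from YAML text, a path, or a mapping.

    Parameters
    ----------
    config_source
        A ``dict`` already in rule-table shape, a path to a YAML file, an open
        text stream, or a YAML string.

    Raises
    ------
    RuleTableError
        If the source does not parse or violates the schema; the message names
        the offending rule where one can be identified.
    """
    if isinstance(config_source, dict):
        raw = config_source
    else:
        try:
            if isinstance(config_source, io.IOBase) or hasattr(config_source, "read"):
                text = config_source.read()
            elif isinstance(config_source, Path) or (
                isinstance(config_source, str)
                and "\n" not in config_source
                and Path(config_source).exists()
            ):
                text = Path(config_source).read_text()
            else:
                text = str(config_source)
            raw = yaml.safe_load(text)
        except (OSError, yaml.YAMLError) as exc:
            raise RuleTableError(f"could not parse rule-table config: {exc}") from exc
    if not isinstance(raw, dict):
        raise RuleTableError("rule-table config must be a mapping at top level")
    try:
        return RuleTable.model_validate(raw)
    except ValueError as exc:
        raise RuleTableError(f"invalid rule table: {exc}") from exc


def classify_product(product: ProductRecord, rules: RuleTable) -> ClassificationResult:
    """Classify one product under a rule table.

    Decision order (first match wins):

    1. ``imputed_status`` override -> that status, ``reason=imputed``;
    2. category is always prohibited -> ``not_permitted``;
    3. nutrient vector absent, or any nutrient required by a criterion of the
       matched rule missing -> ``unclassifiable`` (``reason=missing_data``);
    4. any criterion fails (``observed > limit``) -> ``not_permitted`` with the
       violated criteria listed;
    5. any required trigger flag unknown -> ``unclassifiable``; any trigger
       flag fires -> ``not_permitted``;
    6. otherwise ``permitted``.

    Raises
    ------
    UnknownCategoryError
        If the product's category does not resolve in ``rules``.
    BasisMismatchError
        If the product declares a different reference basis than a criterion
        of its matched rule (no silent per-100g/per-100mL conversion).
    """
    rule = _resolve_rule(product, rules)

    if product.imputed_status is not None:
        return ClassificationResult(
            product_id=product.product_id,
            status=product.imputed_status,
            reason="imputed",
        )

    if rule.mode == "always_prohibited":
        return ClassificationResult(
            product_id=product.product_id,
            status="not_permitted",
            reason="category_prohibition",
        )

    nutrients = product.nutrients
    if nutrients is None:
        return ClassificationResult(
            product_id=product.product_id, status="unclassifiable", reason="missing_data"
        )

    failed: list[FailedCriterion] = []
    any_missing = False
    for criterion in rule.criteria:
        if criterion.basis != nutrients.basis:
            raise BasisMismatchError(
                f"product {product.product_id!r} declares {nutrients.basis} but "
                f"criterion {criterion.nutrient!r} of rule {rule.category_code!r} "
                f"is {criterion.basis}"
            )
        observed = getattr(nutrients, criterion.nutrient)
        if observed is None:
            any_missing = True
        elif observed > criterion.limit:
            failed.append(
                FailedCriterion(
                    criterion=criterion.nutrient,
                    observed=observed,
                    limit=criterion.limit,
                )
            )
    if any_missing:
        return ClassificationResult(
            product_id=product.product_id, status="unclassifiable", reason="missing_data"
        )
    if failed:
        return ClassificationResult(
            product_id=product.product_id,
            status="not_permitted",
            reason="nutrient_limit",
            failed_criteria=tuple(failed),
        )

    fired: list[str] = []
    flag_unknown = False
    for flag in sorted(rule.trigger_flags):
        value = getattr(nutrients, TRIGGER_FLAG_FIELDS[flag])
        if value is None:
            flag_unknown = True
        elif value:
            fired.append(flag)
    if fired:
        return ClassificationResult(
            product_id=product.product_id,
            status="not_permitted",
            reason="trigger_flag",
            fired_flags=tuple(fired),
        )
    if flag_unknown:
        return ClassificationResult(
            product_id=product.product_id, status="unclassifiable", reason="missing_data"
        )

    return ClassificationResult(
        product_id=product.product_id, status="permitted", reason="passed"
    )


def _resolve_rule(product: ProductRecord, rules: RuleTable) -> CategoryRule:
    try:
        return rules.rule_for(product.npm_category)
    except UnknownCategoryError as exc:
        raise UnknownCategoryError(
            f"product {product.product_id!r}: {exc}"
        ) from exc


def classify_products(products, rules: RuleTable) -> list[ClassificationResult]:
    """Classify an iterable of products; result order follows the input."""
    return [classify_product(product, rules) for product in products]
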