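"""Leading-product brand classification and method agreement.

The WHO CLICK monitoring framework classifies a whole brand by a single
leading product — the top seller, or the product most visible on the brand's
website. Here the leading product is an explicit input (designating it is an
editorial act, not a computation), and the brand inherits that product's NPM
decision. :func:`compare_methods` then quantifies percent agreement between
this single-product method and the product-line threshold method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import BrandSetMismatchError, ClickError
from .npm_engine import ProductRecord, RuleTable, classify_product

__all__ = [
    "ClickResult",
    "AgreementReport",
    "classify_brand_click",
    "compare_methods",
    "decisions_to_mapping",
]


@dataclass(frozen=True)
class ClickResult:
    brand_id: str
    leading_product_id: str
    permitted: bool


@dataclass(frozen=True)
class Discordance:
    brand_id: str
    threshold_decision: bool
    click_decision: bool


@dataclass(frozen=True)
class AgreementReport:
    """Concordance between two per-brand boolean decision sets."""

    n_brands: int
    n_concordant: int
    discordant: tuple[Discordance, ...]

    @property
    def pct_agreement(self) -> float:
        return 100.0 * self.n_concordant / self.n_brands

    @property
    def discordant_brands(self) -> frozenset[str]:
        return frozenset(d.brand_id for d in self.discordant)


def classify_brand_click(
    brand_id: str,
    leading_product_id: str,
    products: Iterable[ProductRecord],
    rules: RuleTable,
) -> ClickResult:
    """Classify a brand by its designated leading product.

    Raises
    ------
    ClickError
        If the leading product does not belong to the brand, is not in
        ``products``, or is unclassifiable (no decision can be inherited).
    """
    leading = None
    for product in products:
        if product.product_id == leading_product_id:
            leading = product
            break
    if leading is None:
        raise ClickError(
            f"leading product {leading_product_id!r} for brand {brand_id!r} "
            "not found in the product table"
        )
    if leading.brand_id != brand_id:
        raise ClickError(
            f"leading product {leading_product_id!r} belongs to brand "
            f"{leading.brand_id!r}, not {brand_id!r}"
        )
    result = classify_product(leading, rules)
    if result.status == "unclassifiable":
        raise ClickError(
            f"cannot apply CLICK to brand {brand_id!r}: leading product "
            f"{leading_product_id!r} is unclassifiable ({result.reason})"
        )
    return ClickResult(
        brand_id=brand_id,
        leading_product_id=leading_product_id,
        permitted=result.status == "permitted",
    )


def compare_methods(
    threshold_decisions: Mapping[str, bool],
    click_decisions: Mapping[str, bool],
) -> AgreementReport:
    """Percent agreement between threshold and leading-product decisions.

    Both mappings are brand_id -> permitted and must cover the same brands;
    agreement is symmetric in its arguments.

    Raises
    ------
    BrandSetMismatchError
        If the brand sets differ; the message lists the symmetric difference.
    """
    left, right = set(threshold_decisions), set(click_decisions)
    if left != right:
        diff = sorted(left ^ right)
        raise BrandSetMismatchError(
            f"decision sets cover different brands; symmetric difference: {diff}"
        )
    if not left:
        raise BrandSetMismatchError("cannot compare empty decision sets")
    discordant = tuple(
        Discordance(
            brand_id=brand,
            threshold_decision=threshold_decisions[brand],
            click_decision=click_decisions[brand],
        )
        for brand in sorted(left)
        if threshold_decisions[brand] != click_decisions[brand]
    )
    return AgreementReport(
        n_brands=len(left),
        n_concordant=len(left) - len(discordant),
        discordant=discordant,
    )


def decisions_to_mapping(decisions) -> dict[str, bool]:
    """Collapse ThresholdDecision/ClickResult iterables to brand -> permitted."""
    mapping: dict[str, bool] = {}
    for d in decisions:
        if d.brand_id in mapping and mapping[d.brand_id] != d.permitted:
            raise BrandSetMismatchError(
                f"conflicting decisions for brand {d.brand_id!r}"
            )
        mapping[d.brand_id] = d.permitted
    return mapping
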