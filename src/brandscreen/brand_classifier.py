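"""Brand-level aggregation and marketing-permission thresholds.

A brand's profile counts its products by classification outcome; the
percentage permitted is taken over *classified* products only (products whose
nutrient data was unavailable are excluded from the denominator, matching the
source databases' practice of dropping them with no further adjustment). A
brand is then permitted to market at threshold *t* iff its percent permitted
is at least *t* (inclusive comparison on the unrounded value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .errors import BrandScreenError, UnclassifiableBrandError
from .npm_engine import ClassificationResult

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_MIN_COVERAGE",
    "Sector",
    "BrandProfile",
    "ThresholdDecision",
    "aggregate_brand",
    "aggregate_brands",
    "exclude_low_coverage_brands",
    "apply_threshold",
    "threshold_sweep",
    "round_half_up",
]

logger = logging.getLogger(__name__)

Sector = Literal["packaged_food", "beverage", "fast_food"]

#: Thresholds (percent of products permitted) at which brands are tested.
DEFAULT_THRESHOLDS: tuple[float, ...] = (25.0, 50.0, 75.0, 90.0)

#: Brands with fewer than this fraction of products classifiable are dropped
#: (the fast-food brand with only 13% nutrient coverage was excluded while all
#: retained brands had more).
DEFAULT_MIN_COVERAGE: float = 0.25


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero (display only)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BrandProfile:
    """Per-brand classification counts.

    ``pct_permitted`` is ``None`` for a brand with no classifiable products
    (an *unclassifiable brand*), which cannot take threshold decisions.
    """

    brand_id: str
    sector: Sector
    n_total: int
    n_classified: int
    n_permitted: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_permitted <= self.n_classified <= self.n_total:
            raise BrandScreenError(
                f"brand {self.brand_id!r}: inconsistent counts "
                f"(permitted={self.n_permitted}, classified={self.n_classified}, "
                f"total={self.n_total})"
            )

    @property
    def pct_permitted(self) -> Optional[float]:
        if self.n_classified == 0:
            return None
        return 100.0 * self.n_permitted / self.n_classified

    @property
    def coverage(self) -> float:
        return self.n_classified / self.n_total if self.n_total else 0.0

    @property
    def is_unclassifiable(self) -> bool:
        return self.n_classified == 0


@dataclass(frozen=True)
class ThresholdDecision:
    brand_id: str
    threshold: float
    permitted: bool


def aggregate_brand(
    brand_id: str, results: Iterable[ClassificationResult], sector: Sector
) -> BrandProfile:
    """Aggregate one brand's product classifications into a profile.

    Raises
    ------
    BrandScreenError
        If ``results`` is empty.
    """
    results = list(results)
    if not results:
        raise BrandScreenError(f"brand {brand_id!r}: no classification results")
    n_total = len(results)
    n_classified = sum(r.status != "unclassifiable" for r in results)
    n_permitted = sum(r.status == "permitted" for r in results)
    profile = BrandProfile(
        brand_id=brand_id,
        sector=sector,
        n_total=n_total,
        n_classified=n_classified,
        n_permitted=n_permitted,
    )
    if profile.is_unclassifiable:
        logger.warning("brand %r: no classifiable products", brand_id)
    return profile


def aggregate_brands(
    results: Iterable[ClassificationResult],
    brand_of: dict[str, str],
    sector_of: dict[str, Sector],
) -> list[BrandProfile]:
    """Group per-product results by brand and aggregate each.

    Parameters
    ----------
    brand_of
        Maps product_id -> brand_id.
    sector_of
        Maps brand_id -> sector.
    """
    by_brand: dict[str, list[ClassificationResult]] = {}
    for result in results:
        try:
            brand = brand_of[result.product_id]
        except KeyError:
            raise BrandScreenError(
                f"product {result.product_id!r} has no brand assignment"
            ) from None
        by_brand.setdefault(brand, []).append(result)
    return [
        aggregate_brand(brand, brand_results, sector_of[brand])
        for brand, brand_results in by_brand.items()
    ]


def exclude_low_coverage_brands(
    profiles: Iterable[BrandProfile], min_coverage: float = DEFAULT_MIN_COVERAGE
) -> tuple[list[BrandProfile], list[BrandProfile]]:
    """Split profiles into (kept, excluded) by nutrient-data coverage.

    Brands whose fraction of classifiable products falls below
    ``min_coverage`` are excluded: their classified subset (often beverages
    and sides) does not represent the product line.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise BrandScreenError(f"min_coverage must be in [0, 1], got {min_coverage}")
    kept: list[BrandProfile] = []
    excluded: list[BrandProfile] = []
    for profile in profiles:
        if profile.coverage < min_coverage:
            logger.info(
                "excluding brand %r: coverage %.0f%% below floor %.0f%%",
                profile.brand_id,
                100 * profile.coverage,
                100 * min_coverage,
            )
            excluded.append(profile)
        else:
            kept.append(profile)
    return kept, excluded


def apply_threshold(profile: BrandProfile, threshold: float) -> ThresholdDecision:
    """Decide whether one brand may market at ``threshold`` percent.

    The comparison is inclusive: a brand at exactly the threshold is
    permitted. It uses the unrounded percentage, so 49.6% fails a 50%
    threshold even though it displays as 50.
    """
    pct = profile.pct_permitted
    if pct is None:
        raise UnclassifiableBrandError(
            f"brand {profile.brand_id!r} has no classifiable products; "
            "cannot apply a threshold"
        )
    return ThresholdDecision(
        brand_id=profile.brand_id, threshold=threshold, permitted=pct >= threshold
    )


def threshold_sweep(
    profiles: Sequence[BrandProfile],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply every threshold to every brand.

    Returns
    -------
    decisions
        One row per brand: ``brand_id``, ``sector``, ``pct_permitted`` and one
        boolean column ``permitted_<t>`` per threshold.
    summary
        One row per (sector, threshold): number and percent of that sector's
        brands permitted to market.
    """
    if not thresholds:
        raise BrandScreenError("thresholds must be non-empty")
    rows = []
    for profile in profiles:
        row: dict = {
            "brand_id": profile.brand_id,
            "sector": profile.sector,
            "pct_permitted": profile.pct_permitted,
        }
        for t in thresholds:
            row[f"permitted_{t:g}"] = apply_threshold(profile, t).permitted
        rows.append(row)
    decisions = pd.DataFrame(rows)

    summary_rows = []
    for sector, group in decisions.groupby("sector", sort=True):
        for t in thresholds:
            n_permitted = int(group[f"permitted_{t:g}"].sum())
            summary_rows.append(
                {
                    "sector": sector,
                    "threshold": t,
                    "n_brands": len(group),
                    "n_permitted": n_permitted,
                    "pct_brands_permitted": 100.0 * n_permitted / len(group),
                }
            )
    summary = pd.DataFrame(summary_rows)
    return decisions, summary
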