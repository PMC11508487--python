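"""Readers, writers, shipped fixtures and report rendering.

All tabular I/O is plain CSV with documented column dictionaries. Blank cells
always mean *missing*, never zero. Percentages in rendered reports are rounded
half-up to integers for display; all comparisons elsewhere use unrounded
values.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .brand_classifier import BrandProfile, round_half_up
from .click_comparator import AgreementReport
from .errors import ProductTableError
from .npm_engine import (
    ClassificationResult,
    NutrientVector,
    ProductRecord,
    RuleTable,
    load_rule_table,
)

__all__ = [
    "PRODUCT_COLUMNS",
    "read_products",
    "products_from_dataframe",
    "products_to_dataframe",
    "read_brand_metadata",
    "apply_brand_aliases",
    "write_classifications",
    "read_classifications",
    "write_decision_matrix",
    "read_decision_matrix",
    "rule_table_to_yaml",
    "load_default_rules",
    "load_table2_fixture",
    "load_table3_fixture",
    "load_printed_percentages",
    "render_reports",
    "plot_threshold_summary",
]

#: Column dictionary for product CSVs. Empty cell = missing (never zero).
#: ``sodium_g`` is accepted in place of ``sodium_mg`` (times 1000 on read),
#: the only unit conversion the reader performs.
PRODUCT_COLUMNS: tuple[str, ...] = (
    "product_id",
    "brand_id",
    "name",
    "npm_category",
    "basis",
    "energy_kj",
    "total_fat_g",
    "sat_fat_g",
    "total_sugars_g",
    "sodium_mg",
    "protein_g",
    "added_sugar",
    "non_sugar_sweetener",
    "imputed_status",
)

_NUMERIC_COLUMNS = (
    "energy_kj",
    "total_fat_g",
    "sat_fat_g",
    "total_sugars_g",
    "sodium_mg",
    "protein_g",
)
_FLAG_COLUMNS = ("added_sugar", "non_sugar_sweetener")
_TRUE_WORDS = {"true", "1", "y", "yes"}
_FALSE_WORDS = {"false", "0", "n", "no"}


def read_products(path) -> list[ProductRecord]:
    """Read a product CSV into validated records.

    Raises
    ------
    ProductTableError
        On unknown columns, missing required columns, duplicate product ids,
        non-numeric nutrient cells or otherwise invalid rows; messages
        reference the offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return products_from_dataframe(df)


def products_from_dataframe(df: pd.DataFrame) -> list[ProductRecord]:
    """Validate and type a raw (string) product table."""
    allowed = set(PRODUCT_COLUMNS) | {"sodium_g"}
    unknown = [c for c in df.columns if c not in allowed]
    if unknown:
        raise ProductTableError(f"unknown columns: {unknown}")
    required = {"product_id", "brand_id", "npm_category"}
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise ProductTableError(f"missing required columns: {missing_cols}")
    ids = df["product_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ProductTableError(f"duplicate product_id values: {dupes}")

    records: list[ProductRecord] = []
    for i, raw in enumerate(df.to_dict("records"), start=1):
        cells = {k: str(v).strip() for k, v in raw.items()}
        try:
            records.append(_row_to_record(cells))
        except (ValueError, ProductTableError) as exc:
            raise ProductTableError(f"row {i}: {exc}") from exc
    return records


def _row_to_record(cells: dict[str, str]) -> ProductRecord:
    if not cells.get("product_id"):
        raise ProductTableError("product_id is empty")

    vector_fields: dict[str, object] = {}
    for col in _NUMERIC_COLUMNS:
        value = cells.get(col, "")
        if col == "sodium_mg" and not value and cells.get("sodium_g"):
            vector_fields["sodium_mg"] = 1000.0 * _parse_number(
                cells["sodium_g"], "sodium_g"
            )
            continue
        if value:
            vector_fields[col] = _parse_number(value, col)
    for col in _FLAG_COLUMNS:
        value = cells.get(col, "")
        if value:
            vector_fields[f"{col}_present"] = _parse_bool(value, col)

    basis = cells.get("basis", "")
    nutrients: Optional[NutrientVector] = None
    if vector_fields:
        if not basis:
            raise ProductTableError(
                "basis is required when any nutrient or flag value is present"
            )
        nutrients = NutrientVector(basis=basis, **vector_fields)
    elif basis:
        nutrients = NutrientVector(basis=basis)

    imputed = cells.get("imputed_status", "") or None
    if imputed is not None and imputed not in ("permitted", "not_permitted"):
        raise ProductTableError(
            f"invalid imputed_status {imputed!r}; "
            "expected 'permitted', 'not_permitted' or blank"
        )
    return ProductRecord(
        product_id=cells["product_id"],
        brand_id=cells.get("brand_id", ""),
        name=cells.get("name", ""),
        npm_category=cells.get("npm_category", ""),
        nutrients=nutrients,
        imputed_status=imputed,
    )


def _parse_number(value: str, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ProductTableError(
            f"non-numeric value {value!r} in column {column!r}"
        ) from None


def _parse_bool(value: str, column: str) -> bool:
    word = value.strip().lower()
    if word in _TRUE_WORDS:
        return True
    if word in _FALSE_WORDS:
        return False
    raise ProductTableError(f"invalid boolean {value!r} in column {column!r}")


def products_to_dataframe(records: Iterable[ProductRecord]) -> pd.DataFrame:
    """Serialise records back to the documented column dictionary."""
    rows = []
    for r in records:
        row = {c: "" for c in PRODUCT_COLUMNS}
        row.update(
            product_id=r.product_id,
            brand_id=r.brand_id,
            name=r.name,
            npm_category=r.npm_category,
            imputed_status=r.imputed_status or "",
        )
        nv = r.nutrients
        if nv is not None:
            row["basis"] = nv.basis
            for col in _NUMERIC_COLUMNS:
                value = getattr(nv, col)
                row[col] = "" if value is None else f"{value:g}"
            for col in _FLAG_COLUMNS:
                value = getattr(nv, f"{col}_present")
                row[col] = "" if value is None else ("true" if value else "false")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PRODUCT_COLUMNS))


# ---------------------------------------------------------------------------
# Brand metadata


def read_brand_metadata(path) -> pd.DataFrame:
    """Read brand metadata: brand_id, sector, optional alias_of.

    ``alias_of`` merges sub-brands into the brand a consumer would recognise
    (e.g. a zero-sugar variant line into its parent brand, or a chain's cafe
    sub-brand into the chain).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"brand_id", "sector"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ProductTableError(f"brand metadata missing columns: {missing}")
    if "alias_of" not in df.columns:
        df["alias_of"] = ""
    valid = {"packaged_food", "beverage", "fast_food"}
    bad = df.loc[~df["sector"].isin(valid) & (df["alias_of"] == ""), "brand_id"]
    if len(bad):
        raise ProductTableError(
            f"invalid sector for brands {bad.tolist()}; expected one of {sorted(valid)}"
        )
    dupes = df["brand_id"][df["brand_id"].duplicated()].unique().tolist()
    if dupes:
        raise ProductTableError(f"duplicate brand_id values: {dupes}")
    return df


def apply_brand_aliases(
    records: Iterable[ProductRecord], metadata: pd.DataFrame
) -> tuple[list[ProductRecord], dict[str, str]]:
    """Remap aliased brand ids onto their canonical brand.

    Returns the remapped records and a brand_id -> sector mapping for the
    canonical brands.
    """
    alias = {
        row["brand_id"]: row["alias_of"]
        for _, row in metadata.iterrows()
        if row["alias_of"]
    }
    canonical = metadata[metadata["alias_of"] == ""]
    sector_of = dict(zip(canonical["brand_id"], canonical["sector"]))
    for source, target in alias.items():
        if target not in sector_of:
            raise ProductTableError(
                f"alias target {target!r} for brand {source!r} is not a "
                "canonical brand"
            )
    remapped = [
        r.model_copy(update={"brand_id": alias.get(r.brand_id, r.brand_id)})
        for r in records
    ]
    return remapped, sector_of


# ---------------------------------------------------------------------------
# Classification results


def write_classifications(results: Iterable[ClassificationResult], path) -> None:
    rows = [
        {
            "product_id": r.product_id,
            "status": r.status,
            "reason": r.reason,
            "failed_criteria": ";".join(
                f"{f.criterion}:{f.observed:g}>{f.limit:g}" for f in r.failed_criteria
            ),
            "fired_flags": ";".join(r.fired_flags),
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["product_id", "status", "reason", "failed_criteria", "fired_flags"]
    ).to_csv(path, index=False)


def read_classifications(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Decision matrices (brand x threshold, Y/N cells)


def write_decision_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=False)


def read_decision_matrix(path) -> pd.DataFrame:
    """Read a brand x threshold decision matrix with Y/N cells."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    decision_cols = [c for c in df.columns if c.startswith("permitted_")]
    for col in decision_cols:
        bad = df.loc[~df[col].isin(["Y", "N"]), col]
        if len(bad):
            raise ProductTableError(
                f"invalid decision cells in column {col!r}: {bad.unique().tolist()}"
            )
    return df


# ---------------------------------------------------------------------------
# Rule tables


def rule_table_to_yaml(rules: RuleTable) -> str:
    """Serialise a rule table to the YAML schema :func:`load_rule_table` reads."""
    payload = {
        "table_id": rules.table_id,
        "version": rules.version,
        "rules": [
            {
                "category_code": r.category_code,
                "label": r.label,
                "mode": r.mode,
                **(
                    {
                        "criteria": [
                            {
                                "nutrient": c.nutrient,
                                "comparator": c.comparator,
                                "limit": c.limit,
                                "basis": c.basis,
                            }
                            for c in r.criteria
                        ]
                    }
                    if r.criteria
                    else {}
                ),
                **(
                    {"trigger_flags": sorted(r.trigger_flags)}
                    if r.trigger_flags
                    else {}
                ),
            }
            for r in rules.rules
        ],
    }
    return yaml.safe_dump(payload, sort_keys=False)


# ---------------------------------------------------------------------------
# Shipped fixtures


def _data_path(name: str):
    return resources.files("brandscreen.data").joinpath(name)


def load_default_rules() -> RuleTable:
    """The shipped WPRO-style default rule table (best-effort transcription)."""
    return load_rule_table(_data_path("wpro_default.yaml").read_text())


def load_table2_fixture() -> pd.DataFrame:
    """Brand x threshold decisions for the 51 studied brands (Y/N cells)."""
    with resources.as_file(_data_path("table2_decisions.csv")) as p:
        return read_decision_matrix(p)


def load_table3_fixture() -> pd.DataFrame:
    """20 packaged-food brands: 50%/75% threshold and leading-product decisions."""
    with resources.as_file(_data_path("table3_click.csv")) as p:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    if len(df) != 20:
        raise ProductTableError(
            f"leading-product fixture must have 20 rows, found {len(df)}"
        )
    return df


def load_printed_percentages() -> pd.DataFrame:
    """Per-brand percent-permitted values quoted in the study's prose."""
    with resources.as_file(_data_path("printed_percentages.csv")) as p:
        return pd.read_csv(p, dtype={"pct_permitted": float}, keep_default_na=False)


# ---------------------------------------------------------------------------
# Reports


def render_reports(
    profiles: Sequence[BrandProfile],
    decisions: pd.DataFrame,
    summary: pd.DataFrame,
    out_dir,
    agreement: Optional[AgreementReport] = None,
    method_decisions: Optional[
        tuple[Mapping[str, bool], Mapping[str, bool]]
    ] = None,
) -> dict[str, Path]:
    """Write the standard report files into ``out_dir``.

    Emits a brand-profile table, the brand x threshold decision matrix, a
    per-sector percent-of-brands-permitted summary and, when the
    leading-product comparison is supplied, a per-brand method-comparison
    table plus an agreement summary. Percentages are rounded half-up.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    profile_rows = []
    for p in sorted(profiles, key=lambda p: (p.sector, p.brand_id)):
        profile_rows.append(
            {
                "brand_id": p.brand_id,
                "sector": p.sector,
                "n_products": p.n_total,
                "pct_classified": round_half_up(100 * p.coverage),
                "pct_permitted": (
                    "" if p.pct_permitted is None else round_half_up(p.pct_permitted)
                ),
                "pct_not_permitted": (
                    ""
                    if p.pct_permitted is None
                    else round_half_up(100 - p.pct_permitted)
                ),
            }
        )
    paths["brand_profiles"] = out_dir / "brand_profiles.csv"
    pd.DataFrame(profile_rows).to_csv(paths["brand_profiles"], index=False)

    matrix = decisions.copy()
    for col in [c for c in matrix.columns if c.startswith("permitted_")]:
        matrix[col] = matrix[col].map({True: "Y", False: "N"})
    matrix = matrix.drop(columns=["pct_permitted"], errors="ignore")
    paths["decision_matrix"] = out_dir / "decision_matrix.csv"
    write_decision_matrix(matrix, paths["decision_matrix"])

    sector_summary = summary.copy()
    sector_summary["pct_brands_permitted"] = sector_summary[
        "pct_brands_permitted"
    ].map(round_half_up)
    paths["sector_summary"] = out_dir / "sector_summary.csv"
    sector_summary.to_csv(paths["sector_summary"], index=False)

    if agreement is not None and method_decisions is not None:
        threshold_map, click_map = method_decisions
        comparison_rows = [
            {
                "brand_id": brand,
                "threshold_permitted": "Y" if threshold_map[brand] else "N",
                "click_permitted": "Y" if click_map[brand] else "N",
                "discordant": "*" if threshold_map[brand] != click_map[brand] else "",
            }
            for brand in sorted(threshold_map)
        ]
        paths["method_comparison"] = out_dir / "method_comparison.csv"
        pd.DataFrame(comparison_rows).to_csv(paths["method_comparison"], index=False)
        paths["agreement"] = out_dir / "agreement.json"
        paths["agreement"].write_text(
            json.dumps(
                {
                    "n_brands": agreement.n_brands,
                    "n_concordant": agreement.n_concordant,
                    "pct_agreement": agreement.pct_agreement,
                    "discordant_brands": sorted(agreement.discordant_brands),
                },
                indent=2,
            )
        )
    return paths


def plot_threshold_summary(summary: pd.DataFrame, path) -> None:
    """Grouped bar chart: percent of brands permitted per threshold, by sector."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = summary.pivot(
        index="threshold", columns="sector", values="pct_brands_permitted"
    )
    ax = pivot.plot.bar(rot=0, figsize=(7, 4))
    ax.set_xlabel("Threshold (% of products permitted)")
    ax.set_ylabel("Brands permitted to market (%)")
    ax.set_ylim(0, 100)
    ax.legend(title="Sector")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
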