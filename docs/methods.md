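# Methods

## Problem and model

Marketing restrictions for unhealthy food usually act on individual products
via a nutrient profile model (NPM), but much marketing is *brand-only*
(sponsorship, logos) and names no product. `brandscreen` implements and tests
a brand-level classifier: classify every product of a brand under an NPM,
compute the share of the product line permitted to be marketed to children,
and permit the brand iff that share meets a threshold *t* ∈ {25, 50, 75,
90}%. A single-leading-product shortcut (the WHO CLICK approach: judge the
brand by its top-selling or most visible product) is implemented alongside,
with a percent-agreement comparator between the two methods.

Formally, for brand *b* with classified products C(b) of which P(b) are
individually permitted:

    pct_permitted(b) = 100 · P(b) / C(b)
    permitted_at(b, t) ⇔ pct_permitted(b) ≥ t

The comparison is inclusive and uses the unrounded percentage (a brand at
exactly 50.0% passes the 50% threshold; one at 49.6% does not, even though it
displays as 50). The denominator is *classified* products, not all products:
products without nutrient data carry no information and are dropped with no
reweighting, which is also how the study databases were handled.

## The rule engine

An NPM is pure data (`RuleTable`): each category is either
`always_prohibited` (chocolate/confectionery, energy drinks, edible ices, …)
or `threshold_based` with per-nutrient limits (`observed ≤ limit` passes,
per 100 g or per 100 mL) and optional ingredient triggers (added sugar,
non-sugar sweeteners). Decision order for a product:

1. a manual `imputed_status` override wins (audit reason `imputed`) — this is
   how e.g. coffee-based beverages with no nutrient panel can be hand-coded
   as not permitted;
2. category prohibition (no nutrient data needed);
3. missing data: no nutrient vector at all, or any nutrient referenced by a
   criterion of the matched rule missing → `unclassifiable`. This holds even
   when another criterion already fails on an observed value: the source
   databases miss data essentially all-or-nothing per product, and a single
   uniform rule keeps the audit trail unambiguous;
4. any criterion failure → `not_permitted` with every violated criterion
   recorded (`observed`, `limit`);
5. triggers: a required flag that is unknown → `unclassifiable` (the flag can
   only come from reading the ingredient list, so absence is ignorance, not
   absence of the ingredient); a fired flag → `not_permitted`;
6. otherwise `permitted`.

Per-100g vs per-100mL mismatches between a product and its rule are hard
errors — without density data no conversion is defensible. The only unit
conversion the CSV reader performs is `sodium_g` → mg when that column is
declared.

### The shipped default table

The authoritative WHO Western Pacific limits are published separately and are
not reproduced here; `wpro_default.yaml` is a clearly labelled best-effort
encoding (category structure faithful, numeric limits plausible) intended as
a starting point and schema example. Nothing validated by the test suite
depends on its specific numbers — all quantitative tests run on fixtures or
synthetic tables. Verify each limit against the official publication before
any policy use.

## Brand aggregation, coverage and thresholds

`BrandProfile` keeps the count identity `n_permitted ≤ n_classified ≤
n_total` and exposes `coverage = n_classified / n_total`. Brands below a
coverage floor (default 0.25, configurable) are excluded from threshold
analysis: a brand with 13% coverage is effectively described by its beverages
and sides, not its menu. The floor is a package choice — the study excluded
one such brand without stating a numeric cutoff; 0.25 separates that brand
(13%) from every retained one (≥ ~40%).

Display rounding is half-up to integers and happens only in reports; all
decisions use exact fractions. Threshold monotonicity (the permitted set at a
higher threshold is a subset of the set at a lower one) is an exact
consequence of the definition and is enforced by property tests.

## Leading-product (CLICK) comparison

The leading product is an input column, never inferred: "first visible on the
website" is not computable offline and is exactly the arbitrariness the
threshold method is meant to remove. A brand whose leading product is
unclassifiable raises an error and is excluded from (and reported alongside)
the agreement computation. Agreement is plain percent concordance over the
common brand set; discordant brands are listed individually.

### Known non-reproduction

The study's prose reports 65% agreement between the CLICK method and the 75%
threshold, but a row-by-row recount of its own printed comparison table gives
6 mismatches in 20 brands = 70%. The shipped fixture transcribes the table,
and the test suite asserts the recomputed 70%. Similarly, the abstract's "the
25% threshold permitted 62% of brands" is not supported by the printed
decision matrix (20 of 51 ≈ 39%); the fixtures follow the matrix. Neither
discrepancy is "fixed" — both are documented here and left as properties of
the source tables.

## Synthetic portfolios

The generator exists so every stage is testable without proprietary data. A
`SyntheticSpec` states the world; the defaults are the study's setting:

| parameter | default | meaning |
|---|---|---|
| `n_brands` | 20 / 20 / 12 | packaged-food / beverage / fast-food brands |
| `products_per_brand` | (5, 300) | uniform product-line size range |
| `true_permitted_fraction` | 0.37 / 0.07 / 0.20 | per-sector Bernoulli rate for the true label |
| `missing_rate` | 0.009 / 0.0 / 0.58 | per-sector blanking probability |
| `prohibited_category_fraction` | 0.25 | share of not-permitted products placed in always-prohibited categories |
| `seed` | 0 | single integer driving one `numpy` generator |

`prohibited_category_fraction` is stated nowhere in the source; 0.25 reflects
that several studied brands (confectionery, energy drinks) fail wholly by
category while most not-permitted products fail on limits. It was fixed once,
before any test was run against it.

Labels are assigned *before* blanking, so ground truth exists for products
the pipeline must call unclassifiable. Permitted products get every criterion
nutrient at 10–90% of its limit and required triggers set false;
not-permitted products either land in a prohibited category or exceed exactly
one criterion by 10–100% (or fire one trigger for flag-only rules). Draw
order is fixed (documented in `generate_portfolio`) so a seed pins the full
table byte-for-byte.

What the generator does **not** emulate: real nutrient correlation structure,
category-specific marginal distributions, or informative missingness. A green
recovery test establishes that the pipeline is an unbiased counter of the
stated world, not that any real food supply looks like this.

One subtlety the tests encode: random missingness is only *neutral* (leaves
expected percent permitted unchanged) for prohibition-free rule tables. A
blanked product in an always-prohibited category is still classified — the
category alone decides — so it stays in the denominator while blanked
threshold-category products drop out. This is a feature of the engine
semantics (chocolate without a nutrient panel is still chocolate), and the
neutrality property test therefore uses `prohibited_fraction = 0`.

## Numerical and testing choices

- Comparator is `≤` with strict failure above the limit; values exactly at a
  limit pass ("exceeds" fails).
- Statistical tests use binomial standard errors: parameter recovery at
  n = 1000 products/brand within 3 SE; realised missingness within the 99%
  (±2.576 SE) envelope. Seeds are fixed; hypothesis suites are derandomised.
- The engine is cross-checked against an independent brute-force evaluator
  (criterion-by-criterion re-check living in the test suite, sharing no code
  with the engine) on 1,000 random rule-table/product pairs.
- Degenerate inputs: empty brand result sets, all-unclassifiable brands,
  empty rule tables, duplicate category codes and mismatched brand sets are
  all hard errors with named offenders, never silent defaults.

## Limitations

- The shipped default rule table is a transcription aid, not an authority.
- NPM category assignment is an input; the package does not infer categories
  from product names, and ambiguous assignments must be resolved upstream.
- No market-share weighting, no web scraping, no sales-data ranking of
  leading products.
- Brand-level percentages from the original proprietary database are not
  reproducible; fixture tests cover exactly the computations whose inputs are
  printed.
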