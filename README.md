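# brandscreen

Nutrient-profile-model (NPM) classification of food and beverage **brands**
for child-marketing restrictions.

Product-level NPMs decide whether an individual food may be marketed to
children, but brand-only marketing (sponsorship, logo placement) names no
product. `brandscreen` implements the *threshold* brand classifier — compute
the share of a brand's product line that an NPM individually permits, and
permit the brand iff that share meets a threshold — together with the
single-leading-product (WHO CLICK-style) shortcut and a percent-agreement
comparison between the two. It is aimed at public-health nutrition
researchers and food-policy analysts who have (or can simulate) a product
composition table.

For brand *b* with C(b) classified products, P(b) of them permitted:

```
pct_permitted(b) = 100 · P(b) / C(b)        (denominator: classified products)
permitted_at(b, t)  ⇔  pct_permitted(b) ≥ t,     t ∈ {25, 50, 75, 90} %
```

The NPM itself is config data: a rule table of category-level prohibitions
(confectionery, energy drinks, …), per-nutrient limits (`observed ≤ limit`,
per 100 g / 100 mL) and ingredient triggers (added sugar, non-sugar
sweeteners). A WPRO-style default table ships as a schema example
(`brandscreen/data/wpro_default.yaml`); its limits are a best-effort
transcription — verify against the official model before policy use.

## Worked example

The package ships the published brand × threshold decision matrix and the
20-brand leading-product comparison as fixtures. Comparing the
leading-product method to the 50% threshold:

```python
from brandscreen import load_table3_fixture, compare_methods

t3 = load_table3_fixture()
threshold = dict(zip(t3["brand"], t3["permitted_50"] == "Y"))
click = dict(zip(t3["brand"], t3["click_permitted"] == "Y"))
report = compare_methods(threshold, click)
print(f"{report.n_concordant}/{report.n_brands} brands concordant "
      f"({report.pct_agreement:.0f}% agreement)")
for d in report.discordant:
    print(f"  {d.brand_id}: threshold={'Y' if d.threshold_decision else 'N'} "
          f"click={'Y' if d.click_decision else 'N'}")
```

prints

```
17/20 brands concordant (85% agreement)
  McCain: threshold=Y click=N
  Sanitarium: threshold=N click=Y
  Tegel: threshold=Y click=N
```

i.e. the one-product shortcut agrees with the product-line method for 17 of
20 packaged-food brands; the three exceptions are brands whose most visible
product misrepresents the range (a cereal brand cleared by its flagship
biscuit despite 23% of its line being permitted, and vice versa).

The same pipeline runs end to end on synthetic data with known ground truth:

```bash
brandscreen simulate --seed 7 --out-dir demo
brandscreen report --products demo/products.csv --brands demo/brands.csv \
    --rules demo/rules.yaml --out-dir demo_report
head -4 demo_report/brand_profiles.csv
```

```
brand_id,sector,n_products,pct_classified,pct_permitted,pct_not_permitted
beverage_brand_000,beverage,280,100,7,93
beverage_brand_001,beverage,206,100,6,94
beverage_brand_002,beverage,236,100,6,94
```

Each beverage brand is generated with a true 7% permitted fraction, and the
pipeline recovers it; `sector_summary.csv` then shows the percent of brands
permitted at each threshold (at these defaults: 100% of packaged-food brands
at the 25% threshold, 0% at 50% and above, and no beverage or fast-food
brand at any threshold).

Other CLI subcommands: `classify-products`, `classify-brands`, `sweep`,
`click-compare` (see `brandscreen --help`). Input formats are plain CSV with
column dictionaries documented in `brandscreen.io_reporting`; blank cells
mean *missing*, never zero.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the shipped fixtures and a fresh synthetic portfolio at the
default study-scale parameters: the leading-product vs 50%/75%-threshold
percent agreements with their discordant brand lists, the brand sets gained
when relaxing the 90% → 75% → 50% thresholds, the number of brands permitted
at each threshold, and a full synthetic-pipeline sector summary. The JSON
report is written to `--out`.

## Layout

- `brandscreen.npm_engine` — rule-table schema, validation and the
  per-product classifier with full audit trail
- `brandscreen.brand_classifier` — brand profiles, coverage exclusion,
  threshold decisions and sweeps
- `brandscreen.click_comparator` — leading-product classification and
  percent-agreement reports
- `brandscreen.synthetic_data` — seeded generator for portfolios with known
  ground truth
- `brandscreen.io_reporting` — CSV readers/writers, shipped fixtures, report
  rendering
- `docs/methods.md` — model, assumptions, parameter defaults and known
  limitations (including two documented discrepancies internal to the source
  tables)
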