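# nutriprofile

Nutrient profiling models (NPMs) for restrictive food policy — front-of-pack
warning labels, marketing restrictions, school-food rules — applied to the
packaged-food supply, with South Africa's policy context as the reference
configuration.

An NPM formally classifies a food from its nutrition information panel (NIP,
the per-100 g / per-100 mL declaration). This package implements three model
families over a shared product data model, plus the estimation steps they
need and a supply-level compliance analysis:

* **Chile Warning Octagon 2019 (CWO 2019)** — across-the-board threshold
  model: a product is flagged when energy, total sugar, sodium or saturated
  fat strictly exceeds its per-100 g (solids) or per-100 mL (liquids)
  cut-point; the sugar criterion applies only to products with *added* sugar.
* **SA health-and-nutrition-claims model (SA HNC)** — FSANZ-style scored
  model from draft regulation R429: baseline points for nutrients to limit
  (energy, saturated fat, total sugar, sodium) minus modifying points for
  nutrients to encourage (protein, fibre, fruit/vegetable/nut/legume
  content). Compliant when the final score is strictly below 1 (beverages),
  28 (processed cheese and fats) or 4 (other foods). A *baseline* variant
  awards no modifying points.
* **Proposed SA restrictive model** — Chilean cut-points (solids: 400 mg
  sodium, 10 g total sugar, 4 g saturated fat; liquids: 100 mg, 5 g, 3 g)
  without the energy criterion, plus a non-sugar-sweetener (NSS) criterion
  ("contains any"), gated by qualifying criteria — free-sugar source, added
  sodium, added saturated fat — and a default-excessive rule for missing
  values.

Around the models: WHO-aligned per-energy sugar limits (1 g total sugar per
168 kJ, 1 g free sugar per 336 kJ at the 8400 kJ reference intake),
PAHO-style free-sugar estimation from category rules, NSS detection from
ingredient text with a standardized term list, FVNL banding from ingredient
order and form, cut-point sanity checks against whole-foods composition
extracts, a Table-style supply analysis (category means, regulated counts,
model comparison), and a seeded synthetic-supply generator parameterized to
the published 2018 SA survey statistics (n = 6747) so the full pipeline runs
without the original (on-request) dataset.

## Worked example

```python
from nutriprofile import (NutrientPanel, ProductRecord, classify_cwo,
                          classify_sa_proposed, derive_qualifying_criteria,
                          who_aligned_limit, pct_energy_from_sugar)

juice = ProductRecord(
    product_id="orange-juice", category="fruit_juice", form="liquid",
    panel=NutrientPanel(energy_kJ=190.0, total_sugar_g=10.4, total_fat_g=0.0,
                        sat_fat_g=0.0, sodium_mg=9.0),
    ingredients_text="orange juice")

qual = derive_qualifying_criteria(juice)
print(sorted(classify_cwo(juice, qual=qual, missing="excessive").flags))
print(sorted(classify_sa_proposed(juice, qual=qual).flags))
print(who_aligned_limit(160.7, "total"), who_aligned_limit(160.7, "free"))
print(pct_energy_from_sugar(7.2, 160.7))
```

prints

```
[]
['sugar']
1.0 0.5
76.2
```

The juice carries 10.4 g sugar/100 mL but no added-sugar ingredient, so
Chile's added-sugar qualifier passes it (`[]`) while the proposed model's
free-sugar qualifier counts juice sugar as free and flags it (`['sugar']`).
At the surveyed beverage mean energy density of 160.7 kJ/100 mL the
WHO-aligned limits are 1.0 g total and 0.5 g free sugar per 100 mL, and the
surveyed mean of 7.2 g total sugar supplies 76.2% of beverage energy.

The `examples/` directory holds one short script per capability
(classification, scoring, sugar guidelines, sweetener detection, supply
simulation and comparison, cut-point context); each prints the numbers it
computes with a note on what they mean. A thin CLI wraps the pipeline:

```bash
nutriprofile simulate supply.csv --seed 1 --scale 0.15
nutriprofile profile supply.csv --model cwo2019 --model sa-proposed --out prof/
nutriprofile summarize supply.csv
nutriprofile cutpoints fct.csv
```

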