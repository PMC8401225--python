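"""Classify a few packaged products under the warning-octagon thresholds and
the proposed restrictive model.

Builds three products by hand, derives qualifying criteria from their
ingredient lists, and prints each model's per-nutrient flags.  A flag means
the value strictly exceeds the per-100 g/mL cut-point for a qualified
nutrient; a product is compliant when nothing is flagged.
"""

from nutriprofile import (NutrientPanel, ProductRecord, classify_cwo,
                          classify_sa_proposed, derive_qualifying_criteria)

products = [
    ProductRecord(product_id="cola", category="sodas", form="liquid",
                  panel=NutrientPanel(energy_kJ=180.0, total_sugar_g=10.6,
                                      total_fat_g=0.0, sat_fat_g=0.0,
                                      sodium_mg=10.0),
                  ingredients_text="carbonated water, sugar, caramel colourant"),
    ProductRecord(product_id="orange-juice", category="fruit_juice",
                  form="liquid",
                  panel=NutrientPanel(energy_kJ=190.0, total_sugar_g=10.4,
                                      total_fat_g=0.0, sat_fat_g=0.0,
                                      sodium_mg=9.0),
                  ingredients_text="orange juice"),
    ProductRecord(product_id="salted-crisps", category="snack_foods",
                  form="solid",
                  panel=NutrientPanel(energy_kJ=2100.0, total_sugar_g=1.0,
                                      total_fat_g=30.0, sat_fat_g=12.0,
                                      sodium_mg=650.0),
                  ingredients_text="potato, vegetable oil, salt"),
]

for product in products:
    qual = derive_qualifying_criteria(product)
    cwo = classify_cwo(product, qual=qual, missing="excessive")
    sa = classify_sa_proposed(product, qual=qual)
    print(f"{product.product_id:14s}  CWO 2019: {sorted(cwo.flags) or 'compliant'}"
          f"   proposed: {sorted(sa.flags) or 'compliant'}")

# The juice shows the two models' key difference: it has no added-sugar
# ingredient, so Chile's added-sugar qualifier waves its 10.4 g/100 mL past
# the CWO sugar criterion, while the proposal's free-sugar qualifier counts
# juice sugar as free and flags it.
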