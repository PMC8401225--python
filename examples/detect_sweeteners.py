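"""Detect non-sugar sweeteners in ingredient lists and estimate free sugar.

NSS matching is case-folded with word boundaries, so additive codes (E951)
and synonyms resolve to canonical sweeteners while lookalike tokens
(polysaccharide) never false-match.
"""

from nutriprofile import (NutrientPanel, ProductRecord, detect_nss,
                          estimate_free_sugar, nss_prevalence)

labels = [
    "carbonated water, aspartame, acesulfame K",
    "water, sweetener (E951), flavouring",
    "sugar, cocoa mass, emulsifier",
    "polysaccharide thickener, water",
]
for text in labels:
    det = detect_nss(text)
    print(f"{text!r:55s} -> {sorted(det.matches) or 'none'}")

products = [
    ProductRecord(product_id=f"diet-{i}", category="sodas", form="liquid",
                  panel=NutrientPanel(total_sugar_g=0.0),
                  ingredients_text="carbonated water, sucralose")
    for i in range(5)
] + [
    ProductRecord(product_id=f"regular-{i}", category="sodas", form="liquid",
                  panel=NutrientPanel(total_sugar_g=10.6),
                  ingredients_text="carbonated water, sugar")
    for i in range(4)
]
count, pct = nss_prevalence(products)
print(f"\nNSS prevalence: {count} of {len(products)} sodas ({pct}%)")

free = estimate_free_sugar(products[-1])
print(f"regular soda free sugar: {free.value} g/100 mL ({free.source}) — "
      "all soda sugar counts as free")
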