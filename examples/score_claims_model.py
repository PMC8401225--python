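"""Score a product under the health-and-nutrition-claims points model and
show how 'nutrients to encourage' make the final variant more lenient.

Baseline points accrue from energy, saturated fat, total sugar and sodium;
the final variant subtracts protein, fibre and FVNL points.  A food is
compliant (may carry a claim) when its final score is strictly below 4
(beverages 1, processed cheese and fats 28).
"""

from nutriprofile import (NutrientPanel, ProductRecord, sahnc_compliant,
                          score_sahnc)

muesli = ProductRecord(
    product_id="fruit-muesli", category="breakfast_cereals", form="solid",
    panel=NutrientPanel(energy_kJ=1500.0, total_sugar_g=16.0, total_fat_g=6.0,
                        sat_fat_g=1.5, sodium_mg=120.0, protein_g=9.0,
                        fiber_g=7.0, fvnl_percent=25.0))

for variant in ("baseline", "final"):
    score = score_sahnc(muesli, variant=variant)
    verdict = "compliant" if sahnc_compliant(score) else "non-compliant"
    print(f"{variant:9s}: baseline {score.baseline_points} "
          f"- modifying {score.modifying_points} = {score.final_score}  "
          f"({verdict}, threshold < 4)")
    print(f"           breakdown: {score.breakdown}")

# The same nutrients to limit score ~7 baseline points, but protein and fibre
# points pull the final score under the claims threshold — the leniency that
# motivates restricting policy models to 'nutrients to limit' only.
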