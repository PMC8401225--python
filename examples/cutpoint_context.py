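"""Sanity-check cut-points against a whole-foods composition extract.

Well-placed cut-points should spare whole, unprocessed foods: this prints the
nutrient order statistics of a synthetic whole-foods table and the share of
entries each cut-point would flag.  (The extract here is synthetic — drawn to
resemble a 183-item whole-foods list — because composition tables are
licensed data; ``read_fct`` loads a real extract from delimited text.)
"""

import numpy as np

from nutriprofile import (FCTEntry, NutrientPanel, distribution_summary,
                          flag_rate_under_cutpoints, table5_thresholds)

rng = np.random.default_rng(0)
entries = []
for i in range(183):
    sugar = float(rng.gamma(1.2, 3.0))      # most whole foods are low-sugar
    sodium = float(rng.gamma(1.1, 40.0))
    sat = float(rng.gamma(1.0, 0.8))
    entries.append(FCTEntry(name=f"whole-food-{i}", panel=NutrientPanel(
        total_sugar_g=sugar, sodium_mg=sodium, sat_fat_g=sat,
        total_fat_g=sat * 2.5)))

for nutrient in ("total_sugar_g", "sodium_mg", "sat_fat_g"):
    summary = distribution_summary(entries, nutrient)
    print(f"{nutrient:14s} median {summary['p50']:.1f}  "
          f"p95 {summary['p95']:.1f}  max {summary['max']:.1f}")

rates = flag_rate_under_cutpoints(entries, table5_thresholds())
print("\nshare of whole foods a cut-point would flag:",
      {k: round(v, 3) for k, v in rates.items()})
# Low flag rates mean the thresholds restrict processed products without
# sweeping up natural foods.
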