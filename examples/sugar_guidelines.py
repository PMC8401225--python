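"""WHO-aligned sugar limits and percent-of-energy figures at the surveyed
mean energy densities of the 2018 SA packaged-food supply.

A 10% (total) / 5% (free) share of the 8400 kJ reference intake is 1 g of
total sugar per 168 kJ and 1 g of free sugar per 336 kJ, so a group's mean
energy density converts directly into an aligned g/100 g(-mL) sugar limit.
"""

from nutriprofile import pct_energy_from_sugar, supply_stats, who_aligned_limit

stats = supply_stats()["group_totals"]
for group, unit in (("food", "g/100 g"), ("beverage", "g/100 mL")):
    means = stats[group]["means"]
    energy = means["energy_kJ"]
    print(f"{group}s (mean energy {energy} kJ/100):")
    print(f"  aligned total-sugar limit: {who_aligned_limit(energy, 'total')} {unit}")
    print(f"  aligned free-sugar limit:  {who_aligned_limit(energy, 'free')} {unit}")
    print(f"  actual total sugar {means['total_sugar_g']} {unit} = "
          f"{pct_energy_from_sugar(means['total_sugar_g'], energy)}% of energy")
    print(f"  actual free sugar  {means['free_sugar_g']} {unit} = "
          f"{pct_energy_from_sugar(means['free_sugar_g'], energy)}% of energy")

# Foods carry roughly double the aligned total-sugar density; in beverages
# sugar supplies three-quarters of all energy despite the lower g/100 mL.
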