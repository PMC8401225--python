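# Points-band tables for the South African health-and-nutrition-claims NPM
# (draft R429, derived from the FSANZ nutrient profiling scoring criterion).
# Baseline points accrue for nutrients to limit; modifying points (protein,
# fibre, FVNL) are subtracted in the final variant only.  Band lists are
# ascending thresholds: points = number of thresholds strictly exceeded.
# The tables are editable config; the engine performs no arithmetic beyond
# the band lookups, the protein cap, and the subtraction.
baseline:
  energy_kJ:     [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
  sat_fat_g:     [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  total_sugar_g: [5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
  sodium_mg:     [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
# cheese_or_fat products use extended sat-fat and sodium ladders (1 g and
# 90 mg per point, up to 30 points), per the FSANZ category-3 schedule.
baseline_cheese_or_fat:
  sat_fat_g:     [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17,
                  18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30]
  sodium_mg:     [90, 180, 270, 360, 450, 540, 630, 720, 810, 900, 990, 1080,
                  1170, 1260, 1350, 1440, 1530, 1620, 1710, 1800, 1890, 1980,
                  2070, 2160, 2250, 2340, 2430, 2520, 2610, 2700]
modifying:
  protein_g:     [1.6, 3.2, 4.8, 6.4, 8.0]
  fiber_g:       [0.9, 1.9, 2.9, 3.7, 4.7]
  fvnl_percent:  [40, 60, 80]
  fvnl_points:   [1, 2, 5]      # points awarded at each FVNL band
protein_cap:
  baseline_at_or_above: 13      # protein points ignored when baseline >= 13 ...
  unless_fvnl_points_at_least: 5  # ... unless maximum FVNL points scored
compliance_thresholds:          # compliant iff final score strictly below
  beverage: 1
  cheese_or_fat: 28
  other: 4
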