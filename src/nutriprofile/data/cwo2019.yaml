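# Chile Warning Octagon, final-phase (2019) limits per 100 g / 100 mL.
# Sugar/sodium/saturated-fat limits match the values adopted for the SA
# proposal.  Energy limits are externally sourced from the Chilean food
# labelling regulation (275 kcal/100 g solids, 70 kcal/100 mL liquids,
# converted at 4.184 kJ/kcal); they are not restated in SA policy documents.
name: cwo2019
comparison: gt
includes_energy: true
includes_nss: false
solids:
  sodium_mg: 400
  total_sugar_g: 10
  sat_fat_g: 4
  energy_kJ: 1150.6
liquids:
  sodium_mg: 100
  total_sugar_g: 5
  sat_fat_g: 3
  energy_kJ: 292.88
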