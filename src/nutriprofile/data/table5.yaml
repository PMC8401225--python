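# Proposed South African restrictive NPM cut-points (adapted from the Chilean
# approach).  A product is flagged when a qualified nutrient value is strictly
# greater than its cut-point; NSS is flagged on any presence.
name: sa_proposed
comparison: gt
includes_energy: false
includes_nss: true
solids:
  sodium_mg: 400
  total_sugar_g: 10
  sat_fat_g: 4
liquids:
  sodium_mg: 100
  total_sugar_g: 5
  sat_fat_g: 3
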