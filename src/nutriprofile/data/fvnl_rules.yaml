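# Ordinal rules for estimating fruit/vegetable/nut/legume (FVNL) content from
# an ingredient list, emulating a dietitian's manual banding: ingredient
# order, concentrated vs non-concentrated form, and the FVNL share of
# non-negligible ingredients determine a banded percentage.
bands: [0, 25, 50, 75, 100]
concentrated_markers: [concentrate, concentrated, paste, powder, dried]
concentrated_weight: 2.0
order_penalty: 0.5          # multiplier on the FVNL share when the first
                            # non-negligible ingredient is not an FVNL
negligible_ingredients:
  - water
  - salt
  - iodised salt
  - sea salt
  - spices
  - herbs
  - acidity regulator
  - citric acid
  - ascorbic acid
  - antioxidant
  - preservative
  - firming agent
  - calcium chloride
fvnl_terms:
  - apple
  - apricot
  - banana
  - berry
  - berries
  - grape
  - guava
  - mango
  - orange
  - peach
  - pear
  - pineapple
  - raisin
  - strawberry
  - tomato
  - fruit
  - vegetable
  - vegetables
  - bean
  - beans
  - chickpea
  - chickpeas
  - lentil
  - lentils
  - pea
  - peas
  - soya bean
  - almond
  - almonds
  - cashew
  - cashews
  - peanut
  - peanuts
  - nut
  - nuts
  - carrot
  - carrots
  - onion
  - spinach
  - pumpkin
  - butternut
  - sweetcorn
  - corn
  - mushroom
  - mushrooms
  - potato
  - beetroot
  - cabbage
  - pepper
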