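# Per-category free-sugar estimation rules, applied only when the label does
# not declare free sugar.  Rule kinds:
#   all_free          - every gram of total sugar counts as free (e.g. sodas)
#   none_free         - sugar is intrinsic (lactose, whole fruit/vegetable)
#   fraction          - a fixed share of total sugar counts as free
#   ingredient_driven - all-free when a free-sugar-source token appears in the
#                       ingredient list, otherwise none-free
# Sugars from juices and concentrates count as free sugar by definition, so
# 100% fruit juice defaults to all_free.  `added_sugar_sources` is the
# narrower list used by added-sugar qualifiers (Chile's dialect): juice and
# pulp tokens count as free-sugar sources but not as added sugar.
added_sugar_sources:
  - sugar
  - cane sugar
  - brown sugar
  - invert sugar
  - sucrose
  - glucose
  - fructose
  - dextrose
  - glucose syrup
  - corn syrup
  - high fructose corn syrup
  - honey
  - molasses
  - golden syrup
  - malt extract
free_sugar_only_sources:
  - juice
  - fruit juice
  - fruit juice concentrate
  - apple juice concentrate
  - grape juice concentrate
  - fruit pulp
  - fruit concentrate
  - fruit puree
rules:
  breakfast_cereals:       {kind: all_free}
  cereals_cereal_products: {kind: all_free}
  confectionery_dessert:   {kind: all_free}
  dairy:                   {kind: ingredient_driven}
  fruits_vegetables:       {kind: ingredient_driven}
  vegetables:              {kind: all_free}
  legumes:                 {kind: all_free}
  mixed_dishes:            {kind: all_free}
  protein:                 {kind: all_free}
  snack_foods:             {kind: all_free}
  soups_sauces:            {kind: all_free}
  dairy_drinks:            {kind: ingredient_driven}
  other_beverages:         {kind: all_free}
  sodas:                   {kind: all_free}
  fruit_juice:             {kind: all_free}
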