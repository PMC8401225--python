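# Category taxonomy for the South African packaged-food supply survey (2018).
# 11 food sub-categories + 4 beverage sub-categories.  `parent` defines the
# merged fruits & vegetables group used in regulated-count rollups.
categories:
  breakfast_cereals:      {display: "Breakfast cereals",          is_beverage: false, fvnl_eligible: true}
  cereals_cereal_products: {display: "Cereals & cereal products", is_beverage: false, fvnl_eligible: true}
  confectionery_dessert:  {display: "Confectionery & dessert",    is_beverage: false, fvnl_eligible: true}
  dairy:                  {display: "Dairy",                      is_beverage: false, fvnl_eligible: false}
  fruits_vegetables:      {display: "Fruits & vegetables",        is_beverage: false, fvnl_eligible: true, parent: fruits_vegetables_all}
  vegetables:             {display: "Vegetables",                 is_beverage: false, fvnl_eligible: true, parent: fruits_vegetables_all}
  legumes:                {display: "Legumes",                    is_beverage: false, fvnl_eligible: true}
  mixed_dishes:           {display: "Mixed dishes",               is_beverage: false, fvnl_eligible: true}
  protein:                {display: "Protein",                    is_beverage: false, fvnl_eligible: true}
  snack_foods:            {display: "Snack foods",                is_beverage: false, fvnl_eligible: true}
  soups_sauces:           {display: "Soups & sauces",             is_beverage: false, fvnl_eligible: true}
  dairy_drinks:           {display: "Dairy drinks",               is_beverage: true,  fvnl_eligible: false}
  other_beverages:        {display: "Other beverages",            is_beverage: true,  fvnl_eligible: true}
  sodas:                  {display: "Sodas",                      is_beverage: true,  fvnl_eligible: false}
  fruit_juice:            {display: "100% fruit juice",           is_beverage: true,  fvnl_eligible: true}
parents:
  fruits_vegetables_all: {display: "Fruits & vegetables (merged)"}
aliases:
  "confectionary & dessert": confectionery_dessert
  "100% juice": fruit_juice
  "100 juice": fruit_juice
  "juice": fruit_juice
  "soda": sodas
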