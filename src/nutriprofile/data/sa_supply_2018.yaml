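# Published category-level statistics of the 2018 South African packaged-food
# supply survey (n = 6747): per-category sample sizes, mean nutrient content
# per 100 g (foods) / 100 mL (beverages), NSS-containing product counts, and
# the counts of products regulated under the CWO 2019 model.  These drive the
# synthetic-supply generator defaults and the worked per-energy computations.
category_stats:
  breakfast_cereals:
    n: 110
    means: {energy_kJ: 1588.2, total_sugar_g: 17.2, free_sugar_g: 16.3,
            total_fat_g: 8.9, sat_fat_g: 2.9, trans_fat_g: 0.03, sodium_mg: 210.6}
    nss_count: 0
  cereals_cereal_products:
    n: 254
    means: {energy_kJ: 989.9, total_sugar_g: 3.1, free_sugar_g: 3.2,
            total_fat_g: 6.1, sat_fat_g: 2.4, trans_fat_g: 0.11, sodium_mg: 338.5}
    nss_count: 8
  confectionery_dessert:
    n: 1119
    means: {energy_kJ: 1559.8, total_sugar_g: 38.4, free_sugar_g: 35.1,
            total_fat_g: 14.0, sat_fat_g: 7.7, trans_fat_g: 0.12, sodium_mg: 142.5}
    nss_count: 143
  dairy:
    n: 791
    means: {energy_kJ: 766.5, total_sugar_g: 6.4, free_sugar_g: 3.5,
            total_fat_g: 12.6, sat_fat_g: 8.8, trans_fat_g: 0.33, sodium_mg: 322.1}
    nss_count: 70
  fruits_vegetables:
    n: 196
    means: {energy_kJ: 677.4, total_sugar_g: 29.8, free_sugar_g: 15.2,
            total_fat_g: 2.1, sat_fat_g: 1.2, trans_fat_g: 0.02, sodium_mg: 41.9}
    nss_count: 0
  vegetables:
    n: 510
    means: {energy_kJ: 315.9, total_sugar_g: 3.3, free_sugar_g: 3.3,
            total_fat_g: 3.6, sat_fat_g: 0.7, trans_fat_g: 0.03, sodium_mg: 392.6}
    nss_count: 5
  legumes:
    n: 100
    means: {energy_kJ: 342.7, total_sugar_g: 2.1, free_sugar_g: 2.1,
            total_fat_g: 0.8, sat_fat_g: 0.2, trans_fat_g: 0.03, sodium_mg: 290.3}
    nss_count: 0
  mixed_dishes:
    n: 299
    means: {energy_kJ: 813.0, total_sugar_g: 3.3, free_sugar_g: 3.2,
            total_fat_g: 9.3, sat_fat_g: 4.0, trans_fat_g: 0.17, sodium_mg: 429.2}
    nss_count: 10
  protein:
    n: 602
    means: {energy_kJ: 787.4, total_sugar_g: 1.4, free_sugar_g: 1.4,
            total_fat_g: 9.9, sat_fat_g: 3.5, trans_fat_g: 0.13, sodium_mg: 826.0}
    nss_count: 18
  snack_foods:
    n: 699
    means: {energy_kJ: 2059.4, total_sugar_g: 6.8, free_sugar_g: 6.1,
            total_fat_g: 27.9, sat_fat_g: 7.7, trans_fat_g: 0.06, sodium_mg: 476.8}
    nss_count: 58
  soups_sauces:
    n: 610
    means: {energy_kJ: 676.1, total_sugar_g: 9.7, free_sugar_g: 9.6,
            total_fat_g: 11.2, sat_fat_g: 2.2, trans_fat_g: 0.07, sodium_mg: 746.3}
    nss_count: 35
  dairy_drinks:
    n: 306
    means: {energy_kJ: 255.1, total_sugar_g: 6.0, free_sugar_g: 4.9,
            total_fat_g: 1.8, sat_fat_g: 1.1, trans_fat_g: 0.07, sodium_mg: 43.3}
    nss_count: 58
  other_beverages:
    n: 478
    means: {energy_kJ: 116.7, total_sugar_g: 5.8, free_sugar_g: 4.0,
            total_fat_g: 0.1, sat_fat_g: 0.08, trans_fat_g: 0.004, sodium_mg: 13.4}
    nss_count: 213
  sodas:
    n: 288
    means: {energy_kJ: 125.1, total_sugar_g: 6.9, free_sugar_g: 6.9,
            total_fat_g: 0.04, sat_fat_g: 0.02, trans_fat_g: 0.01, sodium_mg: 18.6}
    nss_count: 160
  fruit_juice:
    n: 385
    means: {energy_kJ: 190.0, total_sugar_g: 10.4, free_sugar_g: 6.0,
            total_fat_g: 0.05, sat_fat_g: 0.02, trans_fat_g: 0.0, sodium_mg: 9.5}
    nss_count: 1
group_totals:
  food:
    n: 5290
    means: {energy_kJ: 1072.8, total_sugar_g: 13.4, free_sugar_g: 11.6,
            total_fat_g: 12.4, sat_fat_g: 5.1, trans_fat_g: 0.12, sodium_mg: 411.2}
    nss_count: 347
  beverage:
    n: 1457
    means: {energy_kJ: 160.7, total_sugar_g: 7.2, free_sugar_g: 5.1,
            total_fat_g: 0.45, sat_fat_g: 0.3, trans_fat_g: 0.01, sodium_mg: 19.7}
    nss_count: 432
  all:
    n: 6747
    means: {energy_kJ: 875.7, total_sugar_g: 12.1, free_sugar_g: 10.7,
            total_fat_g: 9.8, sat_fat_g: 4.1, trans_fat_g: 0.09, sodium_mg: 326.6}
    nss_count: 779
# Products regulated under the CWO 2019 model (overall and per nutrient).
regulated_counts:
  breakfast_cereals:       {n: 110,  overall: 97,   sugar: 74,   sodium: 16,   sat_fat: 31,   energy: 94,   energy_only: 11}
  cereals_cereal_products: {n: 254,  overall: 106,  sugar: 1,    sodium: 71,   sat_fat: 34,   energy: 47,   energy_only: 10}
  confectionery_dessert:   {n: 1119, overall: 1057, sugar: 997,  sodium: 83,   sat_fat: 600,  energy: 912,  energy_only: 12}
  dairy:                   {n: 791,  overall: 515,  sugar: 262,  sodium: 246,  sat_fat: 56,   energy: 74,   energy_only: 3}
  fruits_vegetables_all:   {n: 706,  overall: 293,  sugar: 129,  sodium: 163,  sat_fat: 13,   energy: 29,   energy_only: 8}
  legumes:                 {n: 100,  overall: 28,   sugar: 0,    sodium: 28,   sat_fat: 0,    energy: 3,    energy_only: 0}
  mixed_dishes:            {n: 299,  overall: 211,  sugar: 14,   sodium: 177,  sat_fat: 113,  energy: 36,   energy_only: 3}
  protein:                 {n: 602,  overall: 412,  sugar: 6,    sodium: 390,  sat_fat: 88,   energy: 88,   energy_only: 3}
  snack_foods:             {n: 699,  overall: 564,  sugar: 95,   sodium: 388,  sat_fat: 394,  energy: 552,  energy_only: 35}
  soups_sauces:            {n: 610,  overall: 480,  sugar: 206,  sodium: 416,  sat_fat: 106,  energy: 244,  energy_only: 12}
  food_total:              {n: 5290, overall: 3763, sugar: 1784, sodium: 1978, sat_fat: 1435, energy: 2079, energy_only: 97}
  dairy_drinks:            {n: 306,  overall: 139,  sugar: 135,  sodium: 4,    sat_fat: 0,    energy: 39,   energy_only: 1}
  other_beverages:         {n: 478,  overall: 246,  sugar: 243,  sodium: 1,    sat_fat: 0,    energy: 3,    energy_only: 2}
  sodas:                   {n: 288,  overall: 190,  sugar: 190,  sodium: 0,    sat_fat: 0,    energy: 2,    energy_only: 0}
  fruit_juice:             {n: 385,  overall: 6,    sugar: 3,    sodium: 3,    sat_fat: 0,    energy: 0,    energy_only: 0}
  beverage_total:          {n: 1457, overall: 581,  sugar: 571,  sodium: 8,    sat_fat: 0,    energy: 44,   energy_only: 3}
  all_total:               {n: 6747, overall: 4344, sugar: 2355, sodium: 1986, sat_fat: 1435, energy: 2123, energy_only: 100}
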