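# Example component schema (synthetic, NON-AUTHORITATIVE)
components:
- component_id: whole_grains
  display_name: whole grains
  unit: g/day
  aggregation: group_same_unit
  members:
  - wholegrain_bread
  - barley
  - bulgur
  food_group_18: whole grains
- component_id: refined_grains
  display_name: refined grains
  unit: g/day
  aggregation: group_same_unit
  members:
  - white_bread
  - white_rice
  - pasta
  food_group_18: refined grains
- component_id: legumes
  display_name: legumes
  unit: g/day
  aggregation: group_same_unit
  members:
  - lentils
  - beans
  food_group_18: legumes
- component_id: nuts_seeds
  display_name: nuts seeds
  unit: g/day
  aggregation: group_same_unit
  members:
  - nuts
  - seeds
  food_group_18: nuts and seeds
- component_id: vegetable_oils
  display_name: vegetable oils
  unit: g/day
  aggregation: single
  members: []
  food_group_18: oils
- component_id: olive_oil
  display_name: olive oil
  unit: g/day
  aggregation: single
  members: []
  food_group_18: oils
- component_id: butter
  display_name: butter
  unit: g/day
  aggregation: single
  members: []
  food_group_18: refined fats
- component_id: hydrogenated_fats
  display_name: hydrogenated fats
  unit: g/day
  aggregation: single
  members: []
  food_group_18: refined fats
- component_id: soft_drinks
  display_name: soft drinks
  unit: g/day
  aggregation: single
  members: []
  food_group_18: soft drinks
- component_id: coffee
  display_name: coffee
  unit: g/day
  aggregation: single
  members: []
  food_group_18: coffee/tea/waters
- component_id: tea
  display_name: tea
  unit: g/day
  aggregation: single
  members: []
  food_group_18: coffee/tea/waters
- component_id: processed_foods
  display_name: processed foods
  unit: g/day
  aggregation: group_same_unit
  members:
  - fast_food
  - salty_snacks
  food_group_18: processed foods
- component_id: sweets
  display_name: sweets
  unit: g/day
  aggregation: group_same_unit
  members:
  - sugar
  - confectionery
  food_group_18: processed foods
- component_id: salt
  display_name: salt
  unit: g/day
  aggregation: single
  members: []
  food_group_18: processed foods
- component_id: fruits
  display_name: fruits
  unit: g/day
  aggregation: group_same_unit
  members:
  - apples
  - citrus
  - berries
  - dried_fruit
  - other_fruit
  food_group_18: fruits
- component_id: vegetables
  display_name: vegetables
  unit: g/day
  aggregation: group_same_unit
  members:
  - leafy_veg
  - root_veg
  - tomatoes
  - cucurbits
  - alliums
  - other_veg
  food_group_18: vegetables
- component_id: red_meat
  display_name: red meat
  unit: g/day
  aggregation: single
  members: []
  food_group_18: red meat
- component_id: processed_meat
  display_name: processed meat
  unit: g/day
  aggregation: single
  members: []
  food_group_18: processed meat
- component_id: white_meat
  display_name: white meat
  unit: g/day
  aggregation: single
  members: []
  food_group_18: white meat
- component_id: fish
  display_name: fish
  unit: g/day
  aggregation: single
  members: []
  food_group_18: fish
- component_id: dairy_high_fat
  display_name: dairy high fat
  unit: g/day
  aggregation: single
  members: []
  food_group_18: dairy
- component_id: dairy_low_fat
  display_name: dairy low fat
  unit: g/day
  aggregation: single
  members: []
  food_group_18: dairy
- component_id: eggs
  display_name: eggs
  unit: g/day
  aggregation: single
  members: []
  food_group_18: dairy
- component_id: diet_drinks
  display_name: diet drinks
  unit: g/day
  aggregation: single
  members: []
  food_group_18: diet drinks
- component_id: alcoholic_drinks
  display_name: alcoholic drinks
  unit: g/day
  aggregation: single
  members: []
  food_group_18: alcoholic drinks
- component_id: vitamins_minerals
  display_name: vitamins minerals
  unit: z-units
  aggregation: group_mixed_unit
  members:
  - vitamin_c
  - vitamin_e
  - vitamin_a
  - folate
  - zinc
  - selenium
  - magnesium
  - calcium
  - iron
  food_group_18: null
- component_id: phytochemicals
  display_name: phytochemicals
  unit: z-units
  aggregation: group_mixed_unit
  members:
  - polyphenols
  - carotenoids
  - phytosterols
  - flavonoids
  food_group_18: null
- component_id: fiber
  display_name: fiber
  unit: g/day
  aggregation: single
  members: []
  food_group_18: null
- component_id: omega3
  display_name: omega3
  unit: g/day
  aggregation: single
  members: []
  food_group_18: null
- component_id: dietary_supplements
  display_name: dietary supplements
  unit: units/day
  aggregation: single
  members: []
  food_group_18: null
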