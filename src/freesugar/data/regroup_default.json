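{
  "Fruit juices": "fruit_juice_and_smoothies",
  "Smoothies": "fruit_juice_and_smoothies",
  "Milk": "dairy_products",
  "Yoghurt": "dairy_products",
  "Cheese": "dairy_products",
  "Ice cream": "dairy_products",
  "Carbonated beverage": "soft_drinks_non_diet",
  "Diet carbonated beverage": "soft_drinks_diet",
  "Diet squash": "soft_drinks_diet",
  "Squash": "soft_drinks_non_diet",
  "Cordial": "soft_drinks_non_diet",
  "Fruit juice drinks": "soft_drinks_non_diet",
  "Chocolate": "chocolate_confectionary",
  "Biscuits": "cakes_and_biscuits",
  "Cakes": "cakes_and_biscuits",
  "Sweets": "non_chocolate_confectionary",
  "Sugars": "sugar_and_syrups",
  "Syrups": "sugar_and_syrups",
  "Preserves": "sugar_and_syrups",
  "Puddings": "desserts_and_puddings",
  "RTEBC": "rtebc",
  "Breads": "bread_and_cereals",
  "Cereal dishes": "bread_and_cereals",
  "Rice and pasta": "bread_and_cereals",
  "Fruit": "fruit_and_vegetables",
  "Vegetables": "fruit_and_vegetables",
  "Fruit dishes": "fruit_and_vegetables",
  "Miscellaneous": "other",
  "Sauces": "other",
  "Starchy staples": "other",
  "Composite dishes": "other",
  "Meat and fish": "other",
  "Eggs": "other",
  "Savoury snacks": "other"
}
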