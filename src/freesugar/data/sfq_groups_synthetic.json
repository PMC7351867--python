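[
  {
    "group_id": "sfq_dairy",
    "name": "Milk, yoghurt, cheese and ice-cream (synthetic)",
    "keywords": ["milk", "yoghurt", "cheese", "fromage", "ice", "cream", "custard"],
    "exemplars": ["whole milk plain", "yoghurt strawberry sweetened", "vanilla ice cream"]
  },
  {
    "group_id": "sfq_fruit_veg",
    "name": "Fruit and vegetables (synthetic)",
    "keywords": ["apple", "banana", "carrot", "vegetable", "salad", "pear", "stewed"],
    "exemplars": ["apple raw whole", "banana raw whole", "carrot boiled"]
  },
  {
    "group_id": "sfq_bread_cereal",
    "name": "Breads, rice and pasta (synthetic)",
    "keywords": ["bread", "roll", "porridge", "oats"],
    "exemplars": ["white bread sliced", "wholemeal bread sliced"]
  },
  {
    "group_id": "sfq_soft_drinks",
    "name": "Fizzy drinks and squashes (synthetic)",
    "keywords": ["cola", "lemonade", "squash", "cordial", "fizzy"],
    "exemplars": ["cola carbonated", "lemonade carbonated", "diet cola carbonated"]
  },
  {
    "group_id": "sfq_confectionery",
    "name": "Sweets and chocolate (synthetic)",
    "keywords": ["chocolate", "sweets", "marshmallow", "jelly"],
    "exemplars": ["milk chocolate bar", "jelly sweets"]
  },
  {
    "group_id": "sfq_cakes_biscuits",
    "name": "Cakes and biscuits (synthetic)",
    "keywords": ["biscuit", "cake", "cookie", "scone", "bun"],
    "exemplars": ["digestive biscuit", "sponge cake"]
  },
  {
    "group_id": "sfq_desserts",
    "name": "Puddings and desserts (synthetic)",
    "keywords": ["pudding", "dessert", "trifle"],
    "exemplars": ["rice pudding", "jelly dessert made up"]
  },
  {
    "group_id": "sfq_savoury",
    "name": "Savoury dishes and sauces (synthetic)",
    "keywords": ["pasta", "chicken", "potato", "ketchup", "sauce", "dish"],
    "exemplars": ["pasta cooked plain", "chicken casserole dish"]
  }
]
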