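{
  "description": "Schofield weight-and-height basal metabolic rate equations, MJ/day. bmr = a*weight_kg + b*height_m + c. Bands keyed by sex and age in months.",
  "bands": [
    {"sex": "male", "age_min_months": 0, "age_max_months": 35, "a": 0.0007, "b": 6.349, "c": -2.584, "label": "male_0_3y"},
    {"sex": "male", "age_min_months": 36, "age_max_months": 119, "a": 0.082, "b": 0.545, "c": 1.736, "label": "male_3_10y"},
    {"sex": "male", "age_min_months": 120, "age_max_months": 215, "a": 0.068, "b": 0.574, "c": 2.157, "label": "male_10_18y"},
    {"sex": "female", "age_min_months": 0, "age_max_months": 35, "a": 0.068, "b": 4.281, "c": -1.730, "label": "female_0_3y"},
    {"sex": "female", "age_min_months": 36, "age_max_months": 119, "a": 0.071, "b": 0.677, "c": 1.553, "label": "female_3_10y"},
    {"sex": "female", "age_min_months": 120, "age_max_months": 215, "a": 0.035, "b": 1.948, "c": 0.837, "label": "female_10_18y"}
  ]
}
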