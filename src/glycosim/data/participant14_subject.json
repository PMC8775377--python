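{
  "note": "synthetic subject descriptor for the worked office-worker day; demographics are assumed cohort-typical values, not measured data",
  "id": "participant14",
  "sex": "female",
  "lifestyle": "sedentary",
  "age": 40.0,
  "height": 1.6,
  "weight": 64.0,
  "bmi": 25.0,
  "basal_glucose": 85.0,
  "cho_total": 144.6,
  "n_meals": 4,
  "hr_rest": 75.0,
  "hr_max": 180.0,
  "occupation": "Office worker"
}
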