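# Virtual-population recipe: per sex x lifestyle group counts and
# mean/SD marginals (age in years, basal glucose in mg/dL, BMI in kg/m^2,
# daily carbohydrates in g, height in m). Weight is derived as BMI*height^2.
groups:
  active_male:
    n: 50
    fields:
      age: {mean: 42.0, sd: 14.0}
      basal_glucose: {mean: 88.06, sd: 5.25}
      bmi: {mean: 23.59, sd: 2.4}
      cho_total: {mean: 300.0, sd: 27.0}
      height: {mean: 1.69, sd: 0.06}
  active_female:
    n: 50
    fields:
      age: {mean: 41.0, sd: 12.0}
      basal_glucose: {mean: 88.63, sd: 7.35}
      bmi: {mean: 23.79, sd: 3.12}
      cho_total: {mean: 279.0, sd: 34.0}
      height: {mean: 1.59, sd: 0.07}
  sedentary_male:
    n: 50
    fields:
      age: {mean: 43.0, sd: 14.0}
      basal_glucose: {mean: 89.90, sd: 7.81}
      bmi: {mean: 25.67, sd: 3.4}
      cho_total: {mean: 305.0, sd: 35.0}
      height: {mean: 1.69, sd: 0.06}
  sedentary_female:
    n: 50
    fields:
      age: {mean: 40.0, sd: 12.0}
      basal_glucose: {mean: 90.02, sd: 7.05}
      bmi: {mean: 25.03, sd: 3.22}
      cho_total: {mean: 288.0, sd: 32.0}
      height: {mean: 1.60, sd: 0.06}
# resting heart rate (bpm): cohort-level marginal shared across groups
hr_rest: {mean: 75.4, sd: 7.32, lower: 45.0}
truncation_sd: 3.0
bmi_slope: 0.0
age_floor: 20.0
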