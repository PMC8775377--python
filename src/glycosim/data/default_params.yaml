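# Default parameter set: healthy-subject constants of the extended Bergman
# minimal model (Bergman core + Roy-Parker exercise subsystem + two-pool
# carbohydrate absorption). Override any value per subject or per study.
params:
  p1: 0.0317
  p2: 0.0123
  p3: 4.92e-06
  eta: 0.2659
  gamma: 0.02
  h: null          # null -> threshold equals basal glucose Gb
  Gb: 85.0
  Ib: 7.0
  W: 70.0
  VolG: 117.0
  a1: 0.00158
  a2: 0.056
  a3: 0.00195
  a4: 0.0485
  a5: 0.00125
  a6: 0.075
  T1: 6.0
  K: 0.0108
  r1: 0.007
  r2: 0.009
  r3: 0.028
  r4: 0.035
  meal_yield: 1.0
  u_basal: 8.0
  a_reset_tau: 0.001
units:
  p1: 1/min
  p2: 1/min
  p3: (uU/mL)^-1 min^-2
  eta: 1/min
  gamma: (uU/mL)/(min^2 mg/dL)
  h: mg/dL
  Gb: mg/dL
  Ib: uU/mL
  W: kg
  VolG: dL
  a1: mg/kg/min^2 per %
  a2: 1/min
  a3: mg/kg/min^2 per %
  a4: 1/min
  a5: uU/mL/min^2 per %
  a6: 1/min
  T1: min
  K: mg/kg/min per min
  r1: 1/min
  r2: 1/min
  r3: 1/min
  r4: 1/min
  meal_yield: dimensionless
  u_basal: '% PVO2max'
  a_reset_tau: min
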