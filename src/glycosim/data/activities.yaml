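# Named-activity intensities as % of maximal heart rate, split by lifestyle
# group. Calibrated so sedentary activity keeps oxygen consumption within the
# 8-30 % band and active-lifestyle activity spans up to ~80 % (runs), with
# walks sitting near 30-50 %.
active:
  walk_55: 30.0        # walk, 55 m/min
  walk_70: 37.0        # walk, 70 m/min
  walk_85: 44.0        # walk, 85 m/min
  walk_100: 50.0       # walk, 100 m/min
  run_130: 78.0        # run, 130 m/min
sedentary:
  computer_work: 12.0  # seated computer use
  desk_documentation: 14.0
  reading: 10.0
  mobile_devices: 10.0
  tv: 10.0
  domestic_light: 22.0 # light housework
  sweeping: 27.0       # domestic activity of greater effort
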