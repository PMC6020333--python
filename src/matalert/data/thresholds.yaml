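# Default tiered alert bands for maternal physiologic surveillance.
#
# Cutpoints partition the admissible value axis into
#   (-inf, low_red) | [low_red, low_black) | [low_black, high_black)
#   | [high_black, high_red) | [high_red, +inf)
# i.e. low_red / low_black / normal / high_black / high_red tiers.
# A null cutpoint collapses the adjacent tier (the band is absent).
# "flashing" lists which red tiers are page-triggering at their default
# bound; per-patient overrides may move the page-trigger bound.
schema_version: 1
parameters:
  SBP:        # mmHg
    low_red: 85
    low_black: 90
    high_black: 140
    high_red: 160
    flashing: [low, high]
  DBP:        # mmHg; low diastolic is common under epidural analgesia -> low black only
    low_red: null
    low_black: 50
    high_black: 100
    high_red: 110
    flashing: [high]
  HR:         # beats/min; low red is visual-only (bradycardia pages eliminated)
    low_red: 50
    low_black: 50
    high_black: 120
    high_red: 130
    flashing: [high]
  SpO2:       # percent; visual-only (hypoxemia pages eliminated)
    low_red: 93
    low_black: 95
    high_black: null
    high_red: null
    flashing: []
  temperature:  # degrees C; no low black tier, never pageable
    low_red: 36
    low_black: 36
    high_black: 38
    high_red: 38.5
    flashing: []
shock_index:    # HR / SBP; gated on SBP < 105 and 0-4 h after delivery
  black: 1.2
  red: 1.3
  sbp_gate: 105
  postpartum_window_min: 240
oliguria:       # mL/h; gated on active magnesium infusion
  red: 30
glucose:        # mg/dL; low tiers in [50,70) gated on insulin infusion or OR
  low_red_all: 50
  low_red_conditional: 60
  low_black_conditional: 70
  high_black: 150
  high_red: 280
glucose_staleness:  # hours since last glucose while on insulin infusion
  black_h: 2
  red_h: 3
labs:
  hematocrit:   # percent; < flashing_red pages immediately (severe anemia)
    flashing_red: 18
    black: 21
  platelet_count:  # thousands/uL; visual red only
    red: 80
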