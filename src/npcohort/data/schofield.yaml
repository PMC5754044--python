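# Schofield weight-based basal metabolic rate equations, MJ/day:
# BMR = slope * weight_kg + intercept, by sex and age band.
# The 18-29 band is unreachable for a 40-79 cohort but kept for completeness.
male:
  - {age_min: 18, age_max: 29, slope: 0.063, intercept: 2.896}
  - {age_min: 30, age_max: 59, slope: 0.048, intercept: 3.653}
  - {age_min: 60, age_max: 200, slope: 0.049, intercept: 2.459}
female:
  - {age_min: 18, age_max: 29, slope: 0.062, intercept: 2.036}
  - {age_min: 30, age_max: 59, slope: 0.034, intercept: 3.538}
  - {age_min: 60, age_max: 200, slope: 0.038, intercept: 2.755}
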