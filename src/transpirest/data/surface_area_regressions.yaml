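# Empirical surface-area regressions for seven produce types.
# A [cm^2] = intercept + sum(coefficient * predictor); predictors are
# fresh mass m [g], length L [cm] and diameters d1/d2/d3 [mm].
# Coefficients are stored verbatim to full printed precision.
version: 1
species:
  apple:
    mass_range_g: [73, 300]
    intercept: 61.8323117
    terms:
      mass_g: 1.0484449
    r_squared: 0.9913
    n_samples: 20
  white_asparagus:
    mass_range_g: [40, 85]
    intercept: -6.453975
    terms:
      mass_g: 1.427480
      length_cm: 2.917185
    r_squared: 0.9888
    n_samples: 18
  bell_pepper:
    mass_range_g: [60, 140]
    intercept: 57.441
    terms:
      mass_g: 1.9013
    r_squared: 0.8400
    n_samples: 20
  carrot:
    mass_range_g: [80, 160]
    intercept: -4.13161
    terms:
      mass_g: 0.4304613
      length_cm: 5.2067765
      d1_mm: 0.490815
    r_squared: 0.9107
    n_samples: 20
  radish_tuber:
    mass_range_g: [6, 12]
    intercept: -14.066
    terms:
      d2_mm: 0.57644
      d3_mm: 0.65288
    r_squared: 0.9738
    n_samples: 18
  plum:
    mass_range_g: [34, 96]
    intercept: 26.5435856
    terms:
      mass_g: 0.63359816
    r_squared: 0.9529
    n_samples: 20
  strawberry:
    mass_range_g: [7, 25]
    intercept: 10.6498025
    terms:
      mass_g: 1.862363817
    r_squared: 0.9237
    n_samples: 20
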