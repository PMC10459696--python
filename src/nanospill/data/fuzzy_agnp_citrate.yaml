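# Default fuzzy risk model for citrate-coated spherical silver
# nanoparticles in surface water.
#
# Membership functions are trapezoids given by their four abscissae
# [a, b, c, d] (b == c makes a triangle; a == b or c == d makes a
# shoulder).  Concentration breakpoints are calibrated so the risk curve
# for a citrate sphere is very-low/low below the 22 ng/L limit, flat at
# the medium level on 22-300 ng/L, rises on 300-490 ng/L and saturates
# (high risk) from 490 ng/L on.

category_bands:
  very_low: [0, 25]
  low: [25, 50]
  medium: [50, 75]
  high: [75, 100]

toxicity_model:
  inputs:
    size_nm:
      domain: [0, 100]
      sets:
        small: [0, 0, 20, 40]
        medium: [20, 50, 50, 80]
        large: [60, 80, 100, 100]
    shape:
      categories: [sphere, rod]
    coating:
      categories: [citrate, pvp]
  output:
    name: toxicity
    domain: [0, 100]
    sets:
      low: [0, 0, 20, 40]
      medium: [30, 50, 50, 70]
      high: [60, 80, 100, 100]
  rules:
    # small particles are the most bioavailable; citrate keeps them
    # stable and mobile, PVP sterically hinders uptake one level
    - {size_nm: small, shape: sphere, coating: citrate, toxicity: high}
    - {size_nm: small, shape: rod, coating: citrate, toxicity: high}
    - {size_nm: small, shape: sphere, coating: pvp, toxicity: medium}
    - {size_nm: small, shape: rod, coating: pvp, toxicity: medium}
    - {size_nm: medium, shape: sphere, coating: citrate, toxicity: medium}
    - {size_nm: medium, shape: rod, coating: citrate, toxicity: medium}
    - {size_nm: medium, shape: sphere, coating: pvp, toxicity: low}
    - {size_nm: medium, shape: rod, coating: pvp, toxicity: low}
    - {size_nm: large, shape: sphere, coating: citrate, toxicity: low}
    - {size_nm: large, shape: rod, coating: citrate, toxicity: low}
    - {size_nm: large, shape: sphere, coating: pvp, toxicity: low}
    - {size_nm: large, shape: rod, coating: pvp, toxicity: low}

risk_model:
  inputs:
    concentration_ng_L:
      domain: [0, 600]
      clamp_max: 550
      sets:
        very_low: [0, 0, 3, 19]
        low: [3, 19, 21, 22]
        medium: [21, 22, 300, 490]
        high: [300, 490, 600, 600]
    toxicity:
      domain: [0, 100]
      sets:
        low: [0, 0, 20, 40]
        medium: [30, 50, 50, 70]
        high: [60, 80, 100, 100]
  output:
    name: risk
    domain: [0, 100]
    sets:
      very_low: [0, 0, 10, 30]
      low: [12.5, 37.5, 37.5, 62.5]
      medium: [37.5, 62.5, 62.5, 87.5]
      high: [62.5, 87.5, 100, 100]
  rules:
    - {concentration_ng_L: very_low, toxicity: high, risk: very_low}
    - {concentration_ng_L: low, toxicity: high, risk: low}
    - {concentration_ng_L: medium, toxicity: high, risk: medium}
    - {concentration_ng_L: high, toxicity: high, risk: high}
    - {concentration_ng_L: very_low, toxicity: medium, risk: very_low}
    - {concentration_ng_L: low, toxicity: medium, risk: very_low}
    - {concentration_ng_L: medium, toxicity: medium, risk: low}
    - {concentration_ng_L: high, toxicity: medium, risk: medium}
    - {concentration_ng_L: very_low, toxicity: low, risk: very_low}
    - {concentration_ng_L: low, toxicity: low, risk: very_low}
    - {concentration_ng_L: medium, toxicity: low, risk: very_low}
    - {concentration_ng_L: high, toxicity: low, risk: low}
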