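# Case study 1: accidental AgNP spill 200 m upgradient of a river.
# 2 kg of 10 nm citrate-coated spheres enter the aquifer along a 3 m
# vertical source; the plume discharges into the river and mixes with
# the river flow.
scenario_id: case1_river
source:
  mass_ug: 2.0e+9
  source_length_b_m: 3.0
  distance_L_m: 200.0
aquifer:
  porosity_n: {kind: normal, mean: 0.15, sd: 0.02}
  gradient_g: {kind: uniform, min: 5.0e-4, max: 1.5e-3}
  conductivity_k_m_day: {kind: lognormal, log_mean: 5.5, log_sd: 0.4, units: m/day}
  retardation_F: {kind: uniform, min: 1.0, max: 1.1}
receptor:
  type: river
  flow_QR_m3_s: {kind: lognormal, log_mean: 1.887, log_sd: 0.248, units: m3/s}
nanoparticle:
  size_nm: 10.0
  shape: sphere
  coating: citrate
n_draws: 10000
seed: 1234
thresholds_ng_L: [22.0]
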