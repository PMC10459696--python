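# Case study 2: accidental AgNP spill 600 m from a supply well that
# recharges a 20,000 m³ wetland.  Contaminated pumping lasts between
# 1 h and 65 h at the evapotranspiration-balancing flow of 204 m³/day,
# giving a uniform dilution factor between 4.2e-4 and 2.7e-2 (sampled
# directly here; the (V, q_w, t_m) route reproduces the same bounds).
scenario_id: case2_wetland
source:
  mass_ug: 2.0e+9
  source_length_b_m: 3.0
  distance_L_m: 600.0
aquifer:
  porosity_n: {kind: normal, mean: 0.25, sd: 0.02}
  gradient_g: {kind: uniform, min: 5.0e-4, max: 1.5e-3}
  conductivity_k_m_day: {kind: lognormal, log_mean: 6.1, log_sd: 0.4, units: m/day}
  retardation_F: {kind: uniform, min: 1.0, max: 1.1}
receptor:
  type: wetland
  dilution_factor: {kind: uniform, min: 4.2e-4, max: 2.7e-2}
nanoparticle:
  size_nm: 10.0
  shape: sphere
  coating: citrate
n_draws: 10000
seed: 1234
thresholds_ng_L: [22.0]
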