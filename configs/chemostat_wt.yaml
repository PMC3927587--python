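physiology:
  mu_mg_mean: 0.45 /h
  mu_mg_cv: 0.1
  K_g: 0.1 g/L
  K_d: 0.3
  n_d_mean: 2.0
  n_d_cv: 0.1
  a_d: 0.004 /h
  b_d: 1.0
  s_d: 0.7
  f_ms: 0.4
  K_s: 2e-06 M
  n_s: 2.0
  K_h: 0.05
  m_b0_mean: 1.5e-11 g
  m_b0_cv: 0.15
  a_mb: 1.1
  f_mr: 1.65
  Y_gx: 0.5
  kd_age_offset: 0
  mb_exponent_offset: 0
strains:
- strain_id: wt
  ec_Tsl1: 1e-07 M
  ea_Tsl1: 3e-06 M
  K_Tsl1: 0.2
  fr_Tsl1_cv: 0.3
  tps3_ratio: 1.0
environment:
  mode: chemostat
  D: 0.15 /h
  G_in: 1.0 g/L
  V: 1e-05 L
heat_shock:
  H_a: 0.0
  F_h: 0.0 /h
  phase_offset: 0.0 h
  mode: periodic
  times: []
engine:
  dt: 0.05 h
  duration: 120.0 h
  N_min: 1000
  N_max: 3000
  record_every: 1.0 h
  seed: 0
init:
  cells_per_strain: 20000
  agents_per_strain: 500
toggles:
  scarring_off: false
  damage_split_equal: false
  randomize_mb0_off: false
  randomize_frTsl1_off: false
  randomize_frTps3_off: false
  randomize_mu_off: false
  randomize_nd_off: false
  mean_field_es: false
  mean_field_mD: false
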