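model:
  grid_nx: 25
  grid_ny: 25
  grid_nz: 50
  dx: 0.5
  dy: 0.5
  dz: 2.0
  v_i: 0.25
  v_s: 0.04
  v_d: 0.0001
  v_jsr: 0.01
  v_nsr: 0.01
  D_i: 0.15
  D_sr: 0.06
  D_s: 0.15
  tau_d: 0.2
  tau_s: 0.25
  tau_tr: 30.0
  g_rel: 0.06
  N_RyR: 40
  N_LCC: 5
  nu_up: 0.5
  K_i: 0.69
  K_sr: 4000.0
  B_CSQ: 3300.0
  K_CSQ: 600.0
  buffers:
  - name: TnC
    B_total: 70.0
    k_on: 0.0327
    k_off: 0.0196
    compartment: i
  - name: CaM
    B_total: 24.0
    k_on: 0.034
    k_off: 0.238
    compartment: i
  - name: SRB
    B_total: 47.0
    k_on: 0.115
    k_off: 0.1
    compartment: i
  ncx_params:
    v_ncx: 1150.0
    K_mNa: 87.5
    K_mCa: 1.38
    k_sat: 0.1
    eta: 0.35
  Na_i: 10.0
  Na_o: 136.0
  Ca_o: 1.8
  lcc_params:
    g_lcc: 1.2
    gamma_o: 0.341
    alpha_max: 1.5
    v_half_act: -5.0
    k_act: 6.0
    beta_max: 0.9
    v_half_deact: -25.0
    k_deact: 6.0
    f_max: 0.12
    g_close: 0.3
    k_inact_max: 0.2
    K_inact: 20.0
    r_recover: 0.06
    k_i12: 0.1
    k_i21: 0.005
    k_i2c2: 0.01
    k_c2i2: 0.0005
    v_half_rec: -60.0
    k_rec: 6.0
  ryr_params:
    nu_open_max: 1.4
    K_open: 12.5
    n_open: 3.0
    K_lum: 485.0
    n_lum: 4.0
    k_close: 0.3
    nu_inact_max: 0.2
    K_inact: 50.0
    K_term: 500.0
    theta_term: 1.5
    k_i12: 0.05
    k_i21: 0.001
    k_i2c: 0.0125
    k_i1o: 0.0001
  pacing:
    period: 500.0
    apd: 200.0
    v_rest: -85.0
    v_peak: 20.0
    rise_ms: 2.0
    repol_ms: 10.0
    plateau_droop: 30.0
  dt: 0.1
  dt_diastole: 0.25
  t_fine: 210.0
  seed: 2020
analysis:
  grid_ci:
  - 50.0
  - 400.0
  - 9
  grid_csr:
  - 10.0
  - 80.0
  - 9
  replicates: 8
  n_beats: 100
  seed: null
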