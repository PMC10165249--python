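schema_version: 1
output_dir: results
log_level: INFO
seed: 0
kinetics:
  mu_max_AOO: 0.493
  mu_max_NOO: 0.699
  K_NH4: 1.0
  K_NO2: 0.5
  K_O2_AOO: 0.6
  K_O2_NOO: 0.43
  Y_AOO: 0.15
  Y_NOO: 0.041
  b_AOO: 0.05
  b_NOO: 0.05
  i_N: 0.07
  f_I: 0.1
  rho_X: 141800.0
  T_ref: 20.0
temperature_rules:
  theta_mu_AOO: 1.095
  theta_mu_NOO: 1.06
  theta_b: 1.04
  henry_ref: 43.0
  henry_vant_hoff_K: 1700.0
  D_ref:
    O2: 0.000171072
    NH4: 0.00015552
    NO2: 0.00014688
    NO3: 0.00014688
  biofilm_diffusivity_ratio: 0.42
  perm_ref: 2.5
  perm_activation_energy: 8400.0
  T_ref: 20.0
geometry:
  mode: cylindrical
  Lf: 0.00015
  L_LBL: 5.0e-05
  membrane_outer_radius: 0.000275
  membrane_wall: 0.000135
  gas_pO2: 0.2620799999999999
solver:
  n_nodes: 100
  newton_tol: 1.0e-10
  steady_tol: 0.0001
  probe_interval: 5.0
  dt_max: 2.0
  max_time: 6000.0
matrix:
  temperatures:
  - 8.0
  - 30.0
  thicknesses:
  - 5.0e-05
  - 0.00015
  lbl_thicknesses:
  - 5.0e-05
  - 0.00025
  bulk_NH4: 35.0
batch:
  windows:
  - - 10.0
    - 20.0
  - - 2.5
    - 10.0
  T0: 20.0
synth:
  temperatures:
  - 30.0
  - 24.0
  - 18.0
  - 12.0
  - 8.0
  R_T0: 3.0
  theta: 1.026
  T0: 20.0
  initial_NH4: 50.0
  sample_interval_min: 15.0
  volume: 0.0383
  area: 3.74
  noise_sd: 0.2
  K_app: 1.0
  nitrite_frac_30: 0.074
  nitrite_frac_8: 0.535
  stop_NH4: 1.0
  seed: 0
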