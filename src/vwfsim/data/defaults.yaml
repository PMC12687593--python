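# Full printed default parameterization (reduced units: Dr, kBT, tau).
# Loading this file reproduces every default of the schema explicitly.
seed: 0
n_vwf: 4
n_platelet: 16
duration_tau: 50.0
drag_calibration: 0.36
bond_model: m1
vwf:
  Nm: 30
  sigma: 0.077          # bead diameter [Dr]
  ks: 25000.0           # FENE stiffness [kBT/sigma^2]
  rmax_factor: 2.0      # rmax = 2 sigma
  eps: 16.0             # LJ self-attraction [kBT]
  r_lj_factor: 2.5      # intra-chain LJ cutoff [sigma]
  theta_thres_deg: 150.0
  R_thres_factor: 1.2   # R_thres = 1.2 sigma
platelet:
  Nv: 60
  diameter_um: 2.0
  aspect: 0.3
  area_Dr2: 0.162
  volume_Dr3: 0.0041
repulsion:
  vwf_vwf: 0.077
  platelet_vwf: 0.062
  platelet_platelet: 0.046
  eps: 16.0
flow:
  type: couette
  shear_rate_per_s: 4000.0
domain:
  Lx_um: 10.0
  Ly_um: 10.0
  Lz_um: 10.0
  walls: true
output:
  stride_tau: 0.5
  trajectory: false
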