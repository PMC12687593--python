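# Shear-quench reversibility run with the catch-slip M1 bond model:
# desk-scale suspension of platelets and VWFs in Couette flow.
seed: 1
n_vwf: 4
n_platelet: 16
duration_tau: 20.0
bond_model: m1
flow:
  type: couette
  shear_rate_per_s: 4000.0
domain:
  Lx_um: 16.0
  Ly_um: 4.0
  Lz_um: 6.0
  walls: true
output:
  stride_tau: 0.5
  trajectory: false
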