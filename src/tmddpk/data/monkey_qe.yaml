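schema: tmddpk-params/1
species: cynomolgus
body_weight_kg: 2.8
variant: QE
parameters:
  ka: 0.846      # 1/day, first-order SC absorption
  cl: 12.9       # mL/day, linear clearance
  vc: 116.0      # mL, central volume
  k12: 0.617     # 1/day
  k21: 0.877     # 1/day
  kd: 0.013      # nmol/L, fixed to in vitro monkey T-cell EC50
  rtot: 9.18     # nmol/L, total receptor
  kint: 0.0215   # 1/day, complex internalization
  f1: 1.0        # SC bioavailability (set to 1 to stabilize estimation)
iiv:
  omega_cl: 0.441
  omega_vc: 0.461
  omega_rtot: 1.80
  corr_cl_vc: 0.642
residual_error:
  proportional_cv: 0.201
  additive_sd: 1.11   # nmol/L
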