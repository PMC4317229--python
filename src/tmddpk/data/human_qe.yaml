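schema: tmddpk-params/1
species: human
body_weight_kg: 70.0
variant: QE
# CL, Vc, K12, K21 allometrically scaled from the cynomolgus estimates
# (exponents 0.75, 1, -0.25, -0.25 on the 70/2.8 kg weight ratio);
# KA, F1, Rtot, Kint assumed species-invariant.  Kd is set to the in
# vitro binding EC50 against HUMAN primary T cells (0.031 nmol/L); the
# monkey value 0.013 nmol/L is retained below as an alternative for
# sensitivity analysis.
parameters:
  ka: 0.846
  cl: 144.0
  vc: 2900.0
  k12: 0.276
  k21: 0.392
  kd: 0.031
  rtot: 9.18
  kint: 0.0215
  f1: 1.0
kd_alternative: 0.013
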