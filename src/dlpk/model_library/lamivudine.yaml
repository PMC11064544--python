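# Final once-daily lamivudine 300 mg population-PK model.
# Two-compartment, first-order absorption/elimination, V3/F constrained equal
# to V2/F; allometric weight scaling fixed at 0.75 (CL/F, Q/F) and 1.0 (V2/F);
# proportional residual error with inter-individual variability on its
# magnitude; correlated eta block on (CL/F, V2/F).
drug: lamivudine
compartments: 2
dose_mg: 300.0
tau_h: 24.0
lloq_ug_ml: 0.0025
theta:
  cl: 19.6     # CL/F, L/h (reference: 70 kg, eGFR 99 mL/min/1.73 m2, non-Black)
  v2: 105.0    # V2/F = V3/F, L (reference: 70 kg)
  q: 2.97      # Q/F, L/h
  ka: 2.30     # 1/h
v3_rule: equal_to_v2
covariate_terms:
  - {target: cl, covariate: weight, form: power, reference: 70.0, value: 0.75, fixed: true}
  - {target: cl, covariate: egfr, form: power, reference: 99.0, value: 0.533}
  - {target: cl, covariate: race_black, form: categorical, value: 0.789}  # 1 = Black/African American
  - {target: v2, covariate: weight, form: power, reference: 70.0, value: 1.0, fixed: true}
  - {target: q, covariate: weight, form: power, reference: 70.0, value: 0.75, fixed: true}
random_effects:
  eta_order: [cl, v2, ruv]
  omega2: {cl: 0.0883, v2: 0.158, ruv: 0.247}
  cov: {cl_v2: -0.0531}
residual:
  proportional_sd: 0.359
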