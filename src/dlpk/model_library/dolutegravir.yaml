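# Final once-daily dolutegravir 50 mg population-PK model.
# One-compartment, first-order absorption/elimination; proportional residual
# error with inter-individual variability on its magnitude.
drug: dolutegravir
compartments: 1
dose_mg: 50.0
tau_h: 24.0
lloq_ug_ml: 0.020
theta:
  cl: 0.858    # CL/F, L/h (reference: 79 kg, bilirubin 8 umol/L, non-Hispanic/Latino)
  v2: 16.7     # V/F, L (reference: 79 kg)
  ka: 2.15     # 1/h
covariate_terms:
  - {target: cl, covariate: weight, form: power, reference: 79.0, value: 0.427}
  - {target: cl, covariate: bilirubin, form: power, reference: 8.0, value: -0.153}
  - {target: cl, covariate: ethnicity, form: categorical, value: 0.844}   # 1 = Hispanic/Latino
  - {target: v2, covariate: weight, form: power, reference: 79.0, value: 0.917}
random_effects:
  eta_order: [cl, ruv]
  omega2: {cl: 0.0682, ruv: 0.0567}
residual:
  proportional_sd: 0.341
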