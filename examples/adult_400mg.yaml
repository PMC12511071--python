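# Single 400 mg oral dose in the representative healthy adult.
drug:
  logP: 0.52
  pKa_acid: 4.63
  pKa_base: 9.91
  MW: 171.2368
  solubility: 50
  fup: 0.73
  B2P: 0.97
  GFR_fraction: 1
  TS_spec: 0.74
  CL_renal_ref: 3.2
renal_class: normal
individual:
  age_band: adult
regimen:
  dose_mg: 400
  frequency: single
  days: 2
  formulation: IR
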