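# Base-case values, one-way ranges and PSA distribution families for every
# uncertain model input (2019 US$; probabilities and utilities dimensionless).
# role encodes where the parameter enters: pathway | cost | utility | fold.
parameters:
  - {id: p_opm,                  base: 0.234,  low: 0.085,  high: 0.596,  dist: beta,   role: pathway}
  - {id: sens_ppl,               base: 0.759,  low: 0.651,  high: 0.842,  dist: beta,   role: pathway}
  - {id: sens_lpl,               base: 0.846,  low: 0.747,  high: 0.918,  dist: beta,   role: pathway}
  - {id: specificity,            base: 1.0,    low: 1.0,    high: 1.0,    dist: fixed,  role: pathway}
  - {id: p_cy1p0,                base: 0.064,  low: 0.045,  high: 0.087,  dist: beta,   role: pathway}
  - {id: p_compl_ppl,            base: 0.008,  low: 0.004,  high: 0.012,  dist: beta,   role: pathway}
  - {id: p_compl_lpl,            base: 0.022,  low: 0.0,    high: 0.05,   dist: beta,   role: pathway}
  - {id: p_compl_el,             base: 0.06,   low: 0.03,   high: 0.09,   dist: beta,   role: pathway}
  - {id: p_compl_gastrectomy,    base: 0.216,  low: 0.194,  high: 0.239,  dist: beta,   role: pathway}
  - {id: mort_lpl,               base: 0.0007, low: 0.0,    high: 0.0013, dist: beta,   role: pathway}
  - {id: mort_el,                base: 0.015,  low: 0.0,    high: 0.03,   dist: beta,   role: pathway}
  - {id: mort_gastrectomy,       base: 0.027,  low: 0.003,  high: 0.075,  dist: beta,   role: pathway}
  - {id: cost_ppl,               base: 246,    low: 123,    high: 369,    dist: gamma,  role: cost}
  - {id: cost_lpl,               base: 2213,   low: 1107.5, high: 3319.5, dist: gamma,  role: cost}
  - {id: cost_el,                base: 2065,   low: 1032.5, high: 3097.5, dist: gamma,  role: cost}
  - {id: cost_surgery_dm,        base: 9617,   low: 3521,   high: 16289,  dist: gamma,  role: cost}
  - {id: cost_surgery_indirect,  base: 664,    low: 353,    high: 1217,   dist: gamma,  role: cost}
  - {id: cost_surgery_nonmed,    base: 320,    low: 195,    high: 541,    dist: gamma,  role: cost}
  - {id: cost_adjuvant_cycle,    base: 2635,   low: 2208,   high: 3063,   dist: gamma,  role: cost}
  - {id: cost_chemo_dm,          base: 3697,   low: 1802,   high: 7411,   dist: gamma,  role: cost}
  - {id: cost_chemo_indirect,    base: 1189,   low: 1008,   high: 1906,   dist: gamma,  role: cost}
  - {id: cost_chemo_nonmed,      base: 370,    low: 359,    high: 411,    dist: gamma,  role: cost}
  - {id: cost_palliative_dm,     base: 3109,   low: 1348,   high: 9636,   dist: gamma,  role: cost}
  - {id: cost_palliative_indirect, base: 855,  low: 785,    high: 868,    dist: gamma,  role: cost}
  - {id: cost_palliative_nonmed, base: 367,    low: 349,    high: 371,    dist: gamma,  role: cost}
  - {id: compl_cost_fold,        base: 3.0,    low: 1.5,    high: 4.5,    dist: normal, role: fold}
  - {id: u_adjuvant,             base: 0.68,   low: 0.56,   high: 0.76,   dist: beta,   role: utility}
  - {id: u_postgastrectomy,      base: 0.81,   low: 0.65,   high: 0.97,   dist: beta,   role: utility}
  - {id: u_palliative_surgery,   base: 0.54,   low: 0.52,   high: 0.56,   dist: beta,   role: utility}
  - {id: u_chemotherapy,         base: 0.66,   low: 0.58,   high: 0.73,   dist: beta,   role: utility}
  - {id: u_progressive,          base: 0.40,   low: 0.10,   high: 0.69,   dist: beta,   role: utility}
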