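{
  "version": "1.0",
  "provenance": "Log relative risks transcribed from the published 'model 2' of the Breast Cancer Risk Assessment Tool (Gail and colleagues), white-women formulation, as implemented in standard BCRAT-type software. Category codes: menarche ge14=0, 12to13=1, lt12=2; biopsies 0=0, 1=1, ge2=2; first birth lt20=0, 20to24=1, 25to29=2, nulliparous=2, ge30=3; relatives 0=0, 1=1, ge2=2. The same covariate coefficients are applied to both packaged populations (population-specific attributable-risk complements and rate tables differ); supply your own table for population-specific coefficients. Transcription for research use; verify against an authoritative source before any clinical application.",
  "populations": {
    "White": {
      "beta_menarche": 0.09401,
      "beta_biopsies": 0.52926,
      "beta_biopsies_age_ge50": -0.28804,
      "beta_first_birth": 0.21863,
      "beta_relatives": 0.9583,
      "beta_first_birth_x_relatives": -0.19081,
      "hyperplasia_multiplier": {"no_biopsy": 1.0, "no": 0.93, "yes": 1.82, "unknown": 1.0},
      "one_minus_ar_lt50": 0.5788413,
      "one_minus_ar_ge50": 0.5788413
    },
    "Chinese": {
      "beta_menarche": 0.09401,
      "beta_biopsies": 0.52926,
      "beta_biopsies_age_ge50": -0.28804,
      "beta_first_birth": 0.21863,
      "beta_relatives": 0.9583,
      "beta_first_birth_x_relatives": -0.19081,
      "hyperplasia_multiplier": {"no_biopsy": 1.0, "no": 0.93, "yes": 1.82, "unknown": 1.0},
      "one_minus_ar_lt50": 0.4751981,
      "one_minus_ar_ge50": 0.5031640
    }
  }
}
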