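{
  "_comment": "SYNTHETIC coefficient table for the PCE-style proportional-hazards score. These values are illustrative stand-ins with plausible signs and magnitudes; they are NOT the published pooled-cohort-equation coefficients, which must be supplied by the user as an external JSON of the same shape.",
  "strata": {
    "female": {
      "coefficients": {
        "ln_age": 17.1,
        "ln_age_sq": -1.7,
        "ln_total_chol": 1.0,
        "ln_age*ln_total_chol": -0.2,
        "ln_hdl": -1.2,
        "ln_sbp_treated": 2.0,
        "ln_sbp_untreated": 1.9,
        "smoker": 0.65,
        "diabetes": 0.85
      },
      "mean_lp": 46.8,
      "baseline_survival": 0.966
    },
    "male": {
      "coefficients": {
        "ln_age": 12.3,
        "ln_total_chol": 1.2,
        "ln_age*ln_total_chol": -0.25,
        "ln_hdl": -1.0,
        "ln_sbp_treated": 1.95,
        "ln_sbp_untreated": 1.85,
        "smoker": 0.7,
        "diabetes": 0.7
      },
      "mean_lp": 55.5,
      "baseline_survival": 0.915
    }
  }
}
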