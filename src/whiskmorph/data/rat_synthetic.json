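{
  "species": "rat",
  "provenance": {
    "note": "Synthetic reconstruction: coefficients chosen to reproduce the printed anchor values of the source study's array-morphology model (arclength 11.7 mm at theta_bp=0, upper-bound intercept 0.012 1/mm, elevation-row slope, column-group means of the horizontal emergence angle, species scaling factors). Not a transcription of the displayed equations; the study's deposited data are at https://doi.org/10.5281/zenodo.7992354.",
    "version": "1.0",
    "date": "2026-09-23"
  },
  "array_layout": {
    "A": 4,
    "B": 6,
    "C": 7,
    "D": 7,
    "E": 7
  },
  "upper_bound": {
    "c0": 0.014,
    "c1": 0.03,
    "window": 4.0
  },
  "equations": {
    "theta_bp_from_col": {
      "response": "theta_bp",
      "log_response": false,
      "terms": {
        "1": -67.244,
        "col": 18.5
      },
      "r2": 0.93,
      "aic": NaN,
      "n": 518
    },
    "phi_bp_from_row": {
      "response": "phi_bp",
      "log_response": false,
      "terms": {
        "1": 48.09,
        "row": -10.2,
        "row^2": -1.2
      },
      "r2": 0.95,
      "aic": NaN,
      "n": 518
    },
    "r_bp_from_angles": {
      "response": "r_bp",
      "log_response": false,
      "terms": {
        "1": 12.8,
        "theta_bp": -0.019,
        "theta_bp^2": 0.0004,
        "phi_bp": -0.016
      },
      "r2": 0.5,
      "aic": NaN,
      "n": 518
    },
    "s_from_theta_bp": {
      "response": "S",
      "log_response": true,
      "terms": {
        "1": 3.1986731175506815,
        "theta_bp": -0.0157
      },
      "r2": 0.85,
      "aic": NaN,
      "n": 518
    },
    "a_from_theta_bp": {
      "response": "A",
      "log_response": false,
      "terms": {
        "1": 0.012,
        "theta_bp": 0.00016
      },
      "r2": 0.12,
      "aic": NaN,
      "n": 518
    },
    "theta_w_full": {
      "response": "theta_w",
      "log_response": false,
      "terms": {
        "1": 70.64,
        "theta_bp": 0.497,
        "phi_bp": 0.1
      },
      "r2": 0.4,
      "aic": NaN,
      "n": 518
    },
    "theta_w_reduced": {
      "response": "theta_w",
      "log_response": false,
      "terms": {
        "1": 70.64,
        "theta_bp": 0.497,
        "phi_bp": 0.1
      },
      "r2": 0.4,
      "aic": NaN,
      "n": 518
    },
    "phi_w_from_phi_bp": {
      "response": "phi_w",
      "log_response": false,
      "terms": {
        "1": -2.0,
        "phi_bp": 1.05
      },
      "r2": 0.78,
      "aic": NaN,
      "n": 518
    },
    "zeta_w_full": {
      "response": "zeta_w",
      "log_response": false,
      "terms": {
        "1": 36.0,
        "theta_bp": 0.38,
        "phi_bp": 0.55
      },
      "r2": 0.3,
      "aic": NaN,
      "n": 518
    },
    "zeta_w_reduced": {
      "response": "zeta_w",
      "log_response": false,
      "terms": {
        "1": 36.0,
        "theta_bp": 0.38,
        "phi_bp": 0.55
      },
      "r2": 0.3,
      "aic": NaN,
      "n": 518
    }
  },
  "checksum": "6b78f2a86ddd7ceec6101596a68fa76af9a14e61c04b2c7d2ed9b966803e2eee"
}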