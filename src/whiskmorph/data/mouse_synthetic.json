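{
  "species": "mouse",
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
    "E": 6
  },
  "upper_bound": {
    "c0": 0.012,
    "c1": 0.032,
    "window": 4.0
  },
  "equations": {
    "theta_bp_from_col": {
      "response": "theta_bp",
      "log_response": false,
      "terms": {
        "1": -66.817,
        "col": 19.0
      },
      "r2": 0.95,
      "aic": NaN,
      "n": 447
    },
    "phi_bp_from_row": {
      "response": "phi_bp",
      "log_response": false,
      "terms": {
        "1": 53.656,
        "row": -16.785
      },
      "r2": 0.96,
      "aic": NaN,
      "n": 442
    },
    "r_bp_from_row_col": {
      "response": "r_bp",
      "log_response": false,
      "terms": {
        "1": 8.76525,
        "row": 0.16785,
        "col": -0.228
      },
      "r2": 0.55,
      "aic": NaN,
      "n": 440
    },
    "r_bp_from_angles": {
      "response": "r_bp",
      "log_response": false,
      "terms": {
        "1": 8.5,
        "theta_bp": -0.012,
        "phi_bp": -0.01
      },
      "r2": 0.52,
      "aic": NaN,
      "n": 440
    },
    "s_from_theta_bp": {
      "response": "S",
      "log_response": true,
      "terms": {
        "1": 2.4595888418037104,
        "theta_bp": -0.0165
      },
      "r2": 0.8,
      "aic": NaN,
      "n": 343
    },
    "a_from_theta_bp": {
      "response": "A",
      "log_response": false,
      "terms": {
        "1": 0.011,
        "theta_bp": 0.00015
      },
      "r2": 0.15,
      "aic": NaN,
      "n": 312
    },
    "theta_w_full": {
      "response": "theta_w",
      "log_response": false,
      "terms": {
        "1": 85.0,
        "theta_bp": 0.6
      },
      "r2": 0.35,
      "aic": NaN,
      "n": 442
    },
    "theta_w_reduced": {
      "response": "theta_w",
      "log_response": false,
      "terms": {
        "1": 83.78,
        "theta_bp": 0.639
      },
      "r2": 0.55,
      "aic": NaN,
      "n": 394
    },
    "phi_w_from_phi_bp": {
      "response": "phi_w",
      "log_response": false,
      "terms": {
        "1": 2.0,
        "phi_bp": 1.05
      },
      "r2": 0.75,
      "aic": NaN,
      "n": 445
    },
    "zeta_w_full": {
      "response": "zeta_w",
      "log_response": false,
      "terms": {
        "1": 43.0,
        "phi_bp": 0.47
      },
      "r2": 0.08,
      "aic": NaN,
      "n": 448
    },
    "zeta_w_reduced": {
      "response": "zeta_w",
      "log_response": false,
      "terms": {
        "1": 40.0,
        "theta_bp": 0.4,
        "phi_bp": 0.6
      },
      "r2": 0.35,
      "aic": NaN,
      "n": 309
    }
  },
  "checksum": "f42a0d6b7f2ef791ab5ae6a9f0f2b8ddfb16f81a4b460966dbaad313babb8e9a"
}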