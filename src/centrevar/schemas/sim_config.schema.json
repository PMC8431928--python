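{
  "$defs": {
    "Marginals": {
      "description": "Marginal distributions of case-mix and arrest-context covariates.\n\nDefaults are calibrated to a typical IHCA cohort (median age ~69,\nmedian Charlson 1-2, ~79% witnessed arrests, ~26% shockable rhythm).\nAll are overridable.",
      "properties": {
        "age_bounds": {
          "default": [
            18.0,
            100.0
          ],
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Age Bounds",
          "type": "array"
        },
        "age_mean": {
          "default": 69.0,
          "title": "Age Mean",
          "type": "number"
        },
        "age_sd": {
          "default": 13.0,
          "title": "Age Sd",
          "type": "number"
        },
        "als_mean": {
          "default": 2.5,
          "title": "Als Mean",
          "type": "number"
        },
        "als_patient_sd": {
          "default": 2.0,
          "title": "Als Patient Sd",
          "type": "number"
        },
        "als_physician_24_7_p": {
          "default": 0.833,
          "title": "Als Physician 24 7 P",
          "type": "number"
        },
        "charlson_max": {
          "default": 12,
          "title": "Charlson Max",
          "type": "integer"
        },
        "charlson_mean": {
          "default": 1.8,
          "title": "Charlson Mean",
          "type": "number"
        },
        "female_p": {
          "default": 0.354,
          "title": "Female P",
          "type": "number"
        },
        "intensivist_24_7_p": {
          "default": 0.417,
          "title": "Intensivist 24 7 P",
          "type": "number"
        },
        "location_probs": {
          "additionalProperties": {
            "type": "number"
          },
          "default": {
            "cardiac_care_unit": 0.117,
            "emergency_department": 0.1,
            "icu": 0.15,
            "operating_theatre": 0.046,
            "other": 0.078,
            "radiology": 0.057,
            "ward": 0.452
          },
          "title": "Location Probs",
          "type": "object"
        },
        "pre_cpc_probs": {
          "default": [
            0.778,
            0.145,
            0.052,
            0.024,
            0.001
          ],
          "items": {
            "type": "number"
          },
          "title": "Pre Cpc Probs",
          "type": "array"
        },
        "pre_mrs_probs": {
          "default": [
            0.374,
            0.338,
            0.132,
            0.123,
            0.025,
            0.008
          ],
          "items": {
            "type": "number"
          },
          "title": "Pre Mrs Probs",
          "type": "array"
        },
        "rrs_base_logit": {
          "default": -0.72,
          "title": "Rrs Base Logit",
          "type": "number"
        },
        "shift_probs": {
          "additionalProperties": {
            "type": "number"
          },
          "default": {
            "day": 0.348,
            "evening": 0.494,
            "night": 0.158
          },
          "title": "Shift Probs",
          "type": "object"
        },
        "shockable_p": {
          "default": 0.262,
          "title": "Shockable P",
          "type": "number"
        },
        "training_twice_p": {
          "default": 0.333,
          "title": "Training Twice P",
          "type": "number"
        },
        "weekend_p": {
          "default": 0.28,
          "title": "Weekend P",
          "type": "number"
        },
        "witnessed_p": {
          "default": 0.786,
          "title": "Witnessed P",
          "type": "number"
        }
      },
      "title": "Marginals",
      "type": "object"
    }
  },
  "description": "Ground-truth parameters of a synthetic multicentre cohort.\n\n``tau_outcome`` and ``tau_process`` are the SDs (logit scale) of the\ncentre random intercepts for the latent outcome process and for RRS\nreporting; ``sigma_als_centre`` is the SD in minutes of centre-level\nshifts in mean time to ALS. ``beta`` maps covariate names to log-odds\ncoefficients of the shared outcome linear predictor; ``theta`` holds\nthe five proportional-odds thresholds separating CPC categories 0-5\n(convention: logit P(Y <= k) = theta_k - eta, so positive beta means\nworse outcome).",
  "properties": {
    "beta": {
      "additionalProperties": {
        "type": "number"
      },
      "default": {
        "age": 0.0223,
        "charlson": 0.157,
        "pre_cpc": 0.358,
        "pre_mrs": 0.095
      },
      "title": "Beta",
      "type": "object"
    },
    "mar_driver": {
      "default": "age",
      "title": "Mar Driver",
      "type": "string"
    },
    "mar_slope": {
      "default": 1.0,
      "title": "Mar Slope",
      "type": "number"
    },
    "marginals": {
      "$ref": "#/$defs/Marginals"
    },
    "missing_rates": {
      "additionalProperties": {
        "type": "number"
      },
      "default": {
        "cpc_discharge": 0.017,
        "pre_cpc": 0.036,
        "pre_mrs": 0.039,
        "shift": 0.033,
        "time_to_als": 0.01
      },
      "title": "Missing Rates",
      "type": "object"
    },
    "n_centres": {
      "default": 12,
      "exclusiveMinimum": 0,
      "title": "N Centres",
      "type": "integer"
    },
    "patients_per_centre": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "items": {
            "type": "integer"
          },
          "type": "array"
        }
      ],
      "title": "Patients Per Centre"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "sigma_als_centre": {
      "default": 0.8,
      "minimum": 0.0,
      "title": "Sigma Als Centre",
      "type": "number"
    },
    "tau_outcome": {
      "default": 0.19,
      "minimum": 0.0,
      "title": "Tau Outcome",
      "type": "number"
    },
    "tau_process": {
      "default": 1.1,
      "minimum": 0.0,
      "title": "Tau Process",
      "type": "number"
    },
    "theta": {
      "default": [
        0.53,
        0.95,
        1.17,
        1.29,
        1.34
      ],
      "items": {
        "type": "number"
      },
      "title": "Theta",
      "type": "array"
    }
  },
  "title": "SimConfig",
  "type": "object"
}
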