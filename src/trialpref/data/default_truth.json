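{
  "_comment": "Default generating truth for the synthetic cohort. 'odds_ratios' maps attribute -> [class-1 OR, class-2 OR] for the switch model, relative to the transport-provision reference. Attributes listed under 'non_paper_odds_ratios' have no published estimate; their values were fixed once as plausible defaults (below 1 for the features reported as less influential than transport, above 1 for injection/infusion and study duration) and are NOT published quantities. Intercepts marked 'calibrated' were solved numerically once so that the marginal acceptance rate is 0.71 and the marginal class-2 share is 0.639 under the default covariate marginals.",
  "class_shares": [
    0.361,
    0.639
  ],
  "reference_switch_odds": [
    0.25,
    0.05
  ],
  "odds_ratios": {
    "time_away": [
      11.83,
      0.9
    ],
    "invasive_procedure": [
      7.13,
      2.92
    ],
    "time_home": [
      3.4,
      0.58
    ],
    "results_sharing": [
      2.29,
      1.32
    ],
    "stop_current_medications": [
      1.66,
      11.56
    ],
    "payment": [
      7.37,
      7.81
    ],
    "side_effect_risk": [
      9.04,
      13.89
    ],
    "childcare": [
      0.62,
      0.71
    ],
    "concierge": [
      0.55,
      0.66
    ],
    "continue_after_trial": [
      0.84,
      0.92
    ],
    "placebo_risk": [
      0.95,
      0.88
    ],
    "wear_device": [
      0.73,
      0.81
    ],
    "self_report_mode": [
      0.58,
      0.64
    ],
    "study_hours": [
      0.88,
      0.79
    ],
    "injection_infusion": [
      1.52,
      1.76
    ],
    "study_duration": [
      4.1,
      2.85
    ]
  },
  "non_paper_odds_ratios": [
    "childcare",
    "concierge",
    "continue_after_trial",
    "placebo_risk",
    "wear_device",
    "self_report_mode",
    "study_hours",
    "injection_infusion",
    "study_duration"
  ],
  "initial_decision": {
    "intercept": -1.3275,
    "coefficients": {
      "diag_ge6y": -0.498,
      "conditions_ge3": 0.85,
      "anemia": 0.1,
      "anxiety": -0.007,
      "depression": -0.808,
      "diabetes": -0.206,
      "heart_disease": -0.394,
      "migraine": 0.3,
      "multiple_sclerosis": 0.13,
      "rheumatoid_arthritis": -0.022,
      "cancer_lower": 0.055,
      "cancer_higher": -0.103,
      "treatments_ge3": 0.32,
      "afford_can": -0.357,
      "afford_struggle": -0.224,
      "side_effects_mild": 0.558,
      "side_effects_severe": 0.756,
      "covid_vaccine": 0.269,
      "trial_experience": 0.409,
      "fatigue_ge2": 0.192,
      "mobility_ge2": 0.115,
      "pain_ge2": -0.12,
      "anxious_ge2": -0.551,
      "social_ge3": 0.795,
      "usual_ge3": -0.577,
      "qol_ge8": 0.151,
      "qol_worse_vs_last_year": -0.213,
      "longevity_low": 0.716,
      "future_qol_same_worse": 0.048,
      "age_51_65": -0.459,
      "age_ge66": -0.916,
      "female": -0.177,
      "country_poland": 0.482,
      "country_china": 1.899,
      "no_paid_job": -0.105,
      "university": -0.468,
      "living_alone_no": 0.116,
      "dependents_no": 0.25,
      "high_trust": 0.275,
      "high_altruism": 1.074,
      "survey_version_2": 0.979
    }
  },
  "membership": {
    "intercept": 0.1562,
    "coefficients": {
      "diag_ge6y": -0.156,
      "conditions_ge3": -0.042,
      "anemia": -0.032,
      "anxiety": 0.138,
      "depression": -0.169,
      "diabetes": 0.222,
      "heart_disease": 0.037,
      "migraine": 0.215,
      "multiple_sclerosis": 0.191,
      "rheumatoid_arthritis": 0.013,
      "cancer_lower": -0.087,
      "cancer_higher": 0.126,
      "treatments_ge3": -0.304,
      "afford_can": -0.2,
      "afford_struggle": -0.403,
      "side_effects_mild": 0.097,
      "side_effects_severe": 0.024,
      "covid_vaccine": -0.062,
      "trial_experience": 0.245,
      "fatigue_ge2": -0.288,
      "mobility_ge2": -0.021,
      "pain_ge2": 0.053,
      "anxious_ge2": 0.126,
      "social_ge3": 0.372,
      "usual_ge3": 0.042,
      "qol_ge8": 0.276,
      "qol_worse_vs_last_year": 0.098,
      "longevity_low": 0.096,
      "future_qol_same_worse": -0.13,
      "age_51_65": 0.279,
      "age_ge66": 0.946,
      "female": 0.068,
      "country_poland": 0.218,
      "country_china": 0.195,
      "no_paid_job": -0.213,
      "university": -0.168,
      "living_alone_no": 0.279,
      "dependents_no": 0.094,
      "high_trust": -0.035,
      "high_altruism": -0.02,
      "survey_version_2": 0.154
    }
  },
  "correlation_targets": {
    "country~age_group": 0.63,
    "age_group~employment": 0.61,
    "country~employment": 0.54
  }
}
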