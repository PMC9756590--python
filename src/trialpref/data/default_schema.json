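{
  "country": "US",
  "attributes": [
    {
      "name": "payment",
      "category": "payment_support",
      "levels": ["$0", "$500", "$2,000"],
      "best_index": 2,
      "numeric_values": [0, 500, 2000]
    },
    {
      "name": "transport",
      "category": "payment_support",
      "levels": [
        "Transport costs can be claimed back",
        "Prepaid card for travel",
        "Free transport is provided"
      ],
      "best_index": 2,
      "is_reference": true
    },
    {
      "name": "study_hours",
      "category": "payment_support",
      "levels": [
        "Study undertaken during normal office hours (9-5, Mon-Fri)",
        "Option to participate out of office hours"
      ],
      "best_index": 1
    },
    {
      "name": "childcare",
      "category": "payment_support",
      "levels": ["No childcare provided", "Free childcare provided"],
      "best_index": 1
    },
    {
      "name": "concierge",
      "category": "payment_support",
      "levels": ["No", "Yes"],
      "best_index": 1
    },
    {
      "name": "injection_infusion",
      "category": "administration_procedures",
      "levels": ["Yes", "No"],
      "best_index": 1
    },
    {
      "name": "invasive_procedure",
      "category": "administration_procedures",
      "levels": ["Invasive procedure", "Minimally invasive procedure", "No"],
      "best_index": 2
    },
    {
      "name": "side_effect_risk",
      "category": "treatment_related",
      "levels": ["9 out of 10 (90%)", "2 out of 10 (20%)", "0 out of 10 (0%)"],
      "best_index": 2,
      "numeric_values": [0.9, 0.2, 0.0]
    },
    {
      "name": "placebo_risk",
      "category": "treatment_related",
      "levels": [
        "5 out of 10 (50%)",
        "3 out of 10 (30%)",
        "0 out of 10 (0%, there is no placebo)"
      ],
      "best_index": 2,
      "numeric_values": [0.5, 0.3, 0.0]
    },
    {
      "name": "continue_after_trial",
      "category": "treatment_related",
      "levels": ["No", "Yes"],
      "best_index": 1
    },
    {
      "name": "stop_current_medications",
      "category": "treatment_related",
      "levels": ["Yes", "No"],
      "best_index": 1
    },
    {
      "name": "study_duration",
      "category": "location_time",
      "levels": ["2 years", "1 year", "1 month"],
      "best_index": 2,
      "numeric_values": [24, 12, 1]
    },
    {
      "name": "time_home",
      "category": "location_time",
      "levels": ["30 h / month", "10 h / month", "2 h / month"],
      "best_index": 2,
      "numeric_values": [30, 10, 2]
    },
    {
      "name": "time_away",
      "category": "location_time",
      "levels": ["30 h / month", "10 h / month", "2 h / month"],
      "best_index": 2,
      "numeric_values": [30, 10, 2]
    },
    {
      "name": "wear_device",
      "category": "data_feedback",
      "levels": ["Yes", "No"],
      "best_index": 1
    },
    {
      "name": "self_report_mode",
      "category": "data_feedback",
      "levels": ["Paper-based questionnaire", "Electronic device"],
      "best_index": 1
    },
    {
      "name": "results_sharing",
      "category": "data_feedback",
      "levels": [
        "No",
        "Yes, the average results of everyone who took part",
        "Yes, your own clinical results"
      ],
      "best_index": 2
    }
  ],
  "currency_map": {
    "US": ["$0", "$500", "$2,000"],
    "Poland": ["0 zł", "450 zł", "1,800 zł"],
    "China": ["¥0", "¥500", "¥2,000"]
  }
}
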