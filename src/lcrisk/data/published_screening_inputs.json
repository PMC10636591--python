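{
  "comment": "Published screening-scenario inputs: counts of eligible ever-smokers aged 55-74 contacted, follow-up-tested, LDCT-referred and diagnosed within 6 years, with 2022 GBP unit costs.",
  "params": {
    "cost_phone": 20.57,
    "cost_ldct": 92.77,
    "cost_spiro_visit": 63.42,
    "cost_blood": 7.16,
    "cost_both": 70.58,
    "detect_fraction": 0.2,
    "risk_threshold": 0.0151,
    "horizon": 6.0
  },
  "scenarios": [
    {
      "label": "1: conventional",
      "n_contacted": 106738,
      "n_followup": 22109,
      "n_referred": 22109,
      "n_cases": 819,
      "followup_cost_per_patient": 0.0
    },
    {
      "label": "2: + FEV1 + alcohol + waist",
      "n_contacted": 106738,
      "n_followup": 22109,
      "n_referred": 18930,
      "n_cases": 765,
      "followup_cost_per_patient": 63.42
    },
    {
      "label": "3: + liver blood tests + urate",
      "n_contacted": 106738,
      "n_followup": 22109,
      "n_referred": 18599,
      "n_cases": 757,
      "followup_cost_per_patient": 7.16
    },
    {
      "label": "4: fully expanded",
      "n_contacted": 106738,
      "n_followup": 22109,
      "n_referred": 17468,
      "n_cases": 753,
      "followup_cost_per_patient": 70.58
    }
  ]
}
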