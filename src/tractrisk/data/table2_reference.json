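{
  "description": "Published adult (21+) prevalence estimates with 95% confidence intervals, in percent: the synthetic-microdata citywide aggregates versus city and statewide BRFSS 2005-2010 survey estimates reported by the state public-health department. Used as inputs to the confidence-interval overlap evaluation.",
  "units": "percent",
  "estimates": [
    {"label": "synthetic_microdata", "outcome": "exercise", "prevalence": 64.9, "ci_lower": 62.5, "ci_upper": 67.2},
    {"label": "synthetic_microdata", "outcome": "fruitveg", "prevalence": 17.9, "ci_lower": 15.4, "ci_upper": 20.7},
    {"label": "synthetic_microdata", "outcome": "diabetes", "prevalence": 11.1, "ci_lower": 9.8, "ci_upper": 12.4},
    {"label": "city_brfss", "outcome": "exercise", "prevalence": 66.3, "ci_lower": 64.4, "ci_upper": 68.2},
    {"label": "city_brfss", "outcome": "fruitveg", "prevalence": 20.6, "ci_lower": 18.2, "ci_upper": 22.9},
    {"label": "city_brfss", "outcome": "diabetes", "prevalence": 10.3, "ci_lower": 9.3, "ci_upper": 11.4},
    {"label": "state_brfss", "outcome": "exercise", "prevalence": 78.2, "ci_lower": 77.8, "ci_upper": 78.6},
    {"label": "state_brfss", "outcome": "fruitveg", "prevalence": 27.5, "ci_lower": 26.8, "ci_upper": 28.1},
    {"label": "state_brfss", "outcome": "diabetes", "prevalence": 7.4, "ci_lower": 7.2, "ci_upper": 7.6}
  ]
}
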