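{
  "name": "C2HEST",
  "kind": "score_chart",
  "source_citation": "Li Y-G et al. A simple clinical risk score (C2HEST) for predicting incident atrial fibrillation in Asian subjects. Chest 2019;155:510-518.",
  "terms": [
    {"predictor": "chd", "points": 1},
    {"predictor": "copd", "points": 1},
    {"predictor": "hypertension", "points": 1},
    {"predictor": "age", "transform": {"type": "band", "lo": 75}, "points": 2},
    {"predictor": "chf", "points": 2, "note": "source term: systolic heart failure"},
    {"predictor": "thyroid_disease", "points": 1, "omitted": true,
     "note": "hyperthyroidism; not recorded in the screening cohort"}
  ]
}
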