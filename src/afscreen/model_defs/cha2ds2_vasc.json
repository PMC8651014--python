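{
  "name": "CHA2DS2-VASc",
  "kind": "score_chart",
  "source_citation": "Lip GYH et al. Refining clinical risk stratification for predicting stroke and thromboembolism in atrial fibrillation using a novel risk factor-based approach: the Euro Heart Survey on atrial fibrillation. Chest 2010;137:263-272.",
  "terms": [
    {"predictor": "chf", "points": 1},
    {"predictor": "hypertension", "points": 1},
    {"predictor": "age", "transform": {"type": "band", "lo": 75}, "points": 2},
    {"predictor": "diabetes", "points": 1},
    {"predictor": "stroke_tia", "points": 2},
    {"predictor": "vascular_disease", "transform": {"type": "any_of", "predictors": ["chd", "pad"]}, "points": 1,
     "note": "prior myocardial infarction or peripheral arterial disease (aortic plaque unrecorded)"},
    {"predictor": "age", "transform": {"type": "band", "lo": 65, "hi": 75}, "points": 1},
    {"predictor": "sex", "transform": {"type": "indicator", "level": "female"}, "points": 1}
  ]
}
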