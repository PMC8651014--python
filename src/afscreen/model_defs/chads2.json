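{
  "name": "CHADS2",
  "kind": "score_chart",
  "source_citation": "Gage BF et al. Validation of clinical classification schemes for predicting stroke: results from the National Registry of Atrial Fibrillation. JAMA 2001;285:2864-2870.",
  "terms": [
    {"predictor": "chf", "points": 1},
    {"predictor": "hypertension", "points": 1},
    {"predictor": "age", "transform": {"type": "band", "lo": 75}, "points": 1},
    {"predictor": "diabetes", "points": 1},
    {"predictor": "stroke_tia", "points": 2}
  ]
}
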