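{
  "name": "HATCH",
  "kind": "score_chart",
  "source_citation": "de Vos CB et al. Progression from paroxysmal to persistent atrial fibrillation: clinical correlates and prognosis. J Am Coll Cardiol 2010;55:725-731.",
  "terms": [
    {"predictor": "hypertension", "points": 1},
    {"predictor": "age", "transform": {"type": "band", "lo": 75}, "points": 1},
    {"predictor": "stroke_tia", "points": 2},
    {"predictor": "copd", "points": 1},
    {"predictor": "chf", "points": 2}
  ]
}
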