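{
  "name": "CHARGE-AF",
  "kind": "cox_linear_predictor",
  "source_citation": "Alonso A et al. Simple risk model predicts incidence of atrial fibrillation in a racially and geographically diverse population: the CHARGE-AF consortium. J Am Heart Assoc 2013;2:e000102. Simple-model coefficients.",
  "terms": [
    {"predictor": "age", "transform": {"type": "per_units", "k": 5}, "weight": 0.508},
    {"predictor": "ethnicity", "weight": 0.465, "omitted": true,
     "note": "White race/ethnicity; not recorded in the screening cohort"},
    {"predictor": "height", "transform": {"type": "per_units", "k": 0.10}, "weight": 0.248,
     "note": "per 10 cm; cohort heights are in metres"},
    {"predictor": "weight", "transform": {"type": "per_units", "k": 15}, "weight": 0.115},
    {"predictor": "sbp", "transform": {"type": "per_units", "k": 20}, "weight": 0.197},
    {"predictor": "dbp", "weight": -0.101, "omitted": true,
     "note": "diastolic blood pressure per 10 mmHg; not recorded in the screening cohort"},
    {"predictor": "smoking", "transform": {"type": "indicator", "level": "current"}, "weight": 0.359},
    {"predictor": "antihypertensive_medication", "weight": 0.349},
    {"predictor": "diabetes", "weight": 0.237},
    {"predictor": "chf", "weight": 0.701},
    {"predictor": "chd", "weight": 0.496,
     "note": "proxy: source term is prior myocardial infarction"}
  ]
}
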