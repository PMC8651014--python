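"""Predictor dictionary for the screened-cohort data model.

One row per participant.  All numeric columns are float64 with NaN as the
single missing marker; ``sex`` and ``smoking`` are strings with NaN when
missing.  Binary variables are encoded 0.0/1.0 so that missingness and
vectorised arithmetic behave uniformly.
"""

from __future__ import annotations

ID_COL = "id"

#: Continuous predictors (units documented here once).
CONTINUOUS = {
    "age": "years",
    "height": "m",
    "weight": "kg",
    "bmi": "kg/m^2",  # derived: weight / height^2, computed before imputation
    "sbp": "mmHg",
    "heart_rate": "beats/min",
}

#: Self-reported binary medical histories.
BINARY_HISTORIES = (
    "hypertension",
    "antihypertensive_medication",
    "diabetes",
    "chd",  # prior myocardial infarction or coronary intervention
    "valvular_disease",
    "chf",
    "copd",
    "pad",
    "stroke_tia",
)

CATEGORICAL = {
    "sex": ("female", "male"),
    "smoking": ("current", "former", "never"),
}

#: Pre-screening flags used by the exclusion cascade, and the ECG outcome.
FLAGS = ("prior_af_history", "ecg_performed", "sex_consistent")
OUTCOME = "af_on_ecg"

#: Every column of a canonical cohort table, in fixed order.
ALL_COLUMNS = (
    (ID_COL, "age", "sex", "smoking", "height", "weight", "bmi", "sbp", "heart_rate")
    + BINARY_HISTORIES
    + FLAGS
    + (OUTCOME,)
)

#: Columns that hold 0/1 values (histories, flags, outcome).
BOOLEAN_COLUMNS = BINARY_HISTORIES + FLAGS + (OUTCOME,)

#: Columns a cohort file must provide (everything else may be absent/missing).
MANDATORY_COLUMNS = (ID_COL, "age", "sex", OUTCOME)

#: Predictors that downstream risk models may reference.
PREDICTORS = frozenset(
    ("age", "sex", "smoking", "height", "weight", "bmi", "sbp", "heart_rate")
    + BINARY_HISTORIES
)
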