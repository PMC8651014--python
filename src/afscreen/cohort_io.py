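"""Cohort ingestion, BMI derivation, and the pre-analysis exclusion cascade.

The analysis cohort is a :class:`pandas.DataFrame` with the canonical columns
of :mod:`afscreen.dictionary`.  Readers are tolerant: unparseable or
out-of-vocabulary cells become missing (NaN) and are counted in the returned
parse report; structurally broken files (mandatory column absent) raise.

Exclusions are applied *sequentially* — each record is attributed to the
first rule it violates — so the per-rule counts partition the input.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dictionary as D

logger = logging.getLogger(__name__)

#: Tokens read as missing, case-insensitive (plus the empty field).
NA_TOKENS = frozenset({"", "na", "nan", "null", "none", "."})

_TRUE = frozenset({"1", "true", "yes", "y", "t"})
_FALSE = frozenset({"0", "false", "no", "n", "f"})

_SEX_VOCAB = {"female": "female", "f": "female", "male": "male", "m": "male"}
_SMOKING_VOCAB = {s: s for s in D.CATEGORICAL["smoking"]}

#: Fixed order of the exclusion cascade.
EXCLUSION_RULES = (
    "prior_af_history",
    "no_ecg",
    "inconsistent_sex",
    "age_below_45",
    "bmi_below_18",
)


class SchemaError(ValueError):
    """A cohort file is structurally unusable (mandatory column missing)."""


@dataclass
class ExclusionReport:
    """Per-rule removal tally of the sequential exclusion cascade."""

    initial: int
    removed: list[tuple[str, int]]
    final: int

    def __post_init__(self) -> None:
        if self.initial - sum(n for _, n in self.removed) != self.final:
            raise ValueError("exclusion counts do not partition the input")

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "removed": [{"rule": r, "n": n} for r, n in self.removed],
            "final": self.final,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ParseReport:
    """Counts of cells coerced to missing during ingestion."""

    bad_values: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.bad_values.values())


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _parse_boolean(raw: pd.Series, colname: str, report: ParseReport) -> pd.Series:
    s = raw.str.strip().str.lower()
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    out[s.isin(_TRUE)] = 1.0
    out[s.isin(_FALSE)] = 0.0
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE) | s.isin(NA_TOKENS) | s.isna())
    if bad.any():
        report.bad_values[colname] = report.bad_values.get(colname, 0) + int(bad.sum())
        logger.warning("%d unparseable value(s) in column %r set to missing", bad.sum(), colname)
    return out


def _parse_category(raw: pd.Series, vocab: dict, colname: str, report: ParseReport) -> pd.Series:
    s = raw.str.strip().str.lower()
    out = s.map(vocab)
    bad = out.isna() & ~(s.isin(NA_TOKENS) | s.isna())
    if bad.any():
        report.bad_values[colname] = report.bad_values.get(colname, 0) + int(bad.sum())
        logger.warning("%d out-of-vocabulary value(s) in column %r set to missing", bad.sum(), colname)
    return out


def _parse_numeric(raw: pd.Series, colname: str, report: ParseReport) -> pd.Series:
    s = raw.str.strip()
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & ~(s.str.lower().isin(NA_TOKENS) | s.isna())
    if bad.any():
        report.bad_values[colname] = report.bad_values.get(colname, 0) + int(bad.sum())
        logger.warning("%d non-numeric value(s) in column %r set to missing", bad.sum(), colname)
    return out


def read_cohort(
    path,
    mapping: dict[str, str] | None = None,
    delimiter: str | None = None,
    with_report: bool = False,
):
    """Read a delimited participant table into a canonical cohort frame.

    Parameters
    ----------
    path
        Delimited text file with a header row (comma or tab; auto-detected
        when ``delimiter`` is None).
    mapping
        Canonical-name -> source-column mapping.  Canonical names absent from
        the mapping fall back to an identity lookup; columns still absent
        become all-missing (flags default to their permissive value instead:
        no prior AF, ECG performed, sex consistent).
    with_report
        Also return a :class:`ParseReport` of coerced cells.

    Raises
    ------
    SchemaError
        If a mandatory column (id, age, sex, AF outcome) cannot be located.
    """
    delimiter = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    mapping = dict(mapping or {})
    report = ParseReport()

    def source(col: str) -> pd.Series | None:
        name = mapping.get(col, col)
        return raw[name] if name in raw.columns else None

    for col in D.MANDATORY_COLUMNS:
        if source(col) is None:
            raise SchemaError(f"mandatory column {col!r} not found in {path}")

    out = pd.DataFrame(index=raw.index)
    out[D.ID_COL] = source(D.ID_COL).str.strip()
    for col in ("age", "height", "weight", "bmi", "sbp", "heart_rate"):
        s = source(col)
        out[col] = _parse_numeric(s, col, report) if s is not None else np.nan
    out["sex"] = _parse_category(source("sex"), _SEX_VOCAB, "sex", report)
    s = source("smoking")
    out["smoking"] = (
        _parse_category(s, _SMOKING_VOCAB, "smoking", report) if s is not None else np.nan
    )
    for col in D.BINARY_HISTORIES + (D.OUTCOME,):
        s = source(col)
        out[col] = _parse_boolean(s, col, report) if s is not None else np.nan
    flag_defaults = {"prior_af_history": 0.0, "ecg_performed": 1.0, "sex_consistent": 1.0}
    for col in D.FLAGS:
        s = source(col)
        out[col] = _parse_boolean(s, col, report) if s is not None else flag_defaults[col]

    out = out[list(D.ALL_COLUMNS)]
    return (out, report) if with_report else out


def write_cohort(cohort: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Emit a cohort frame as delimited text (missing cells empty)."""
    out = cohort.copy()
    for col in D.BOOLEAN_COLUMNS:
        if col in out.columns:
            obs = out[col].notna()
            out[col] = out[col].astype(object)
            out.loc[obs, col] = out.loc[obs, col].astype(int)
    out.to_csv(path, sep=delimiter, index=False, na_rep="")


def compute_bmi(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive BMI = weight / height**2 wherever both inputs are present.

    Idempotent; rows with missing height or weight keep a missing BMI.
    Non-positive heights or weights are rejected, naming the offending ids.
    """
    bad = (cohort["height"] <= 0) | (cohort["weight"] <= 0)
    if bad.any():
        ids = cohort.loc[bad, D.ID_COL].tolist()[:5]
        raise ValueError(f"non-positive height/weight for record(s) {ids}")
    out = cohort.copy()
    out["bmi"] = out["weight"] / out["height"] ** 2
    return out


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the pre-analysis exclusion cascade.

    Order: established AF history, no screening ECG, inconsistent sex, age
    below 45 years, BMI below 18 kg/m^2.  Each record counts against the
    first rule it violates, so the report's tallies partition the input.
    Records with missing BMI are retained (imputation handles them).
    """
    n0 = len(cohort)
    remaining = cohort
    removed: list[tuple[str, int]] = []
    predicates = {
        "prior_af_history": lambda df: df["prior_af_history"] == 1,
        "no_ecg": lambda df: df["ecg_performed"] == 0,
        "inconsistent_sex": lambda df: df["sex_consistent"] == 0,
        "age_below_45": lambda df: df["age"] < 45,
        "bmi_below_18": lambda df: df["bmi"] < 18,
    }
    for rule in EXCLUSION_RULES:
        hit = predicates[rule](remaining).fillna(False)
        removed.append((rule, int(hit.sum())))
        remaining = remaining.loc[~hit]
    report = ExclusionReport(initial=n0, removed=removed, final=len(remaining))
    return remaining.reset_index(drop=True), report
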