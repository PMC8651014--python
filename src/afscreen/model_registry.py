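"""Declarative risk prediction models and their evaluation.

A model is data, not code: a JSON/YAML document listing terms, each a
predictor plus a transform and either a regression weight (equation models)
or an integer point value (score charts).  The engine is model-agnostic —
adding a model means writing a definition file, not code.

Cox-derived equations (e.g. CHARGE-AF) are handled as linear predictors
pushed through a logistic link whose intercept is recalibrated to the
cohort prevalence with the slope fixed at 1 ("calibration-in-the-large");
baseline survival is deliberately not modelled because the target here is
*prevalent* disease at a single screening visit.  Source-model predictors
with no counterpart in the cohort dictionary (ethnicity, diastolic blood
pressure, thyroid disease, ...) are carried as ``omitted`` terms: they
contribute nothing to the evaluation but preserve the published definition.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import dictionary as D

EQUATION_KINDS = ("logistic_equation", "cox_linear_predictor")


class Transform(BaseModel):
    """How a raw predictor value maps into a term value."""

    model_config = ConfigDict(extra="forbid")

    type: Literal["identity", "per_units", "indicator", "band", "any_of"]
    k: Optional[float] = None          # per_units: value / k
    level: Optional[str] = None        # indicator: 1 if category == level
    lo: Optional[float] = None         # band: 1 if lo <= value < hi
    hi: Optional[float] = None
    predictors: Optional[list[str]] = None  # any_of: 1 if any flag is set

    @model_validator(mode="after")
    def _check_args(self) -> "Transform":
        if self.type == "per_units" and (self.k is None or self.k <= 0):
            raise ValueError("per_units transform needs k > 0")
        if self.type == "indicator" and not self.level:
            raise ValueError("indicator transform needs a level")
        if self.type == "band" and self.lo is None and self.hi is None:
            raise ValueError("band transform needs lo and/or hi")
        if self.type == "any_of" and not self.predictors:
            raise ValueError("any_of transform needs a predictor list")
        return self


class PredictorTerm(BaseModel):
    model_config = ConfigDict(extra="forbid")

    predictor: str
    transform: Transform = Transform(type="identity")
    weight: Optional[float] = None
    points: Optional[int] = None
    omitted: bool = False
    note: Optional[str] = None

    @model_validator(mode="after")
    def _weight_xor_points(self) -> "PredictorTerm":
        if (self.weight is None) == (self.points is None):
            raise ValueError("exactly one of weight/points must be set")
        return self


class RiskModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    kind: Literal["logistic_equation", "cox_linear_predictor", "score_chart"]
    terms: list[PredictorTerm]
    original_intercept: Optional[float] = None
    source_citation: str = ""
    restrictions: Optional[str] = None

    @field_validator("terms")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("a model needs at least one term")
        return v

    @model_validator(mode="after")
    def _check_terms(self) -> "RiskModel":
        for t in self.terms:
            if self.kind == "score_chart" and t.points is None:
                raise ValueError(f"{self.name}: score-chart term {t.predictor!r} needs points")
            if self.kind in EQUATION_KINDS and t.weight is None:
                raise ValueError(f"{self.name}: equation term {t.predictor!r} needs a weight")
            if t.omitted:
                continue
            referenced = (
                t.transform.predictors if t.transform.type == "any_of" else [t.predictor]
            )
            for p in referenced:
                if p not in D.PREDICTORS:
                    raise ValueError(
                        f"{self.name}: unknown predictor {p!r} (mark the term omitted "
                        "or add the variable to the cohort dictionary)"
                    )
        return self

    @property
    def active_terms(self) -> list[PredictorTerm]:
        return [t for t in self.terms if not t.omitted]


def _term_values(term: PredictorTerm, cohort: pd.DataFrame) -> np.ndarray:
    tr = term.transform
    if tr.type == "any_of":
        acc = np.zeros(len(cohort), dtype=bool)
        for p in tr.predictors:
            acc |= cohort[p].to_numpy(float) == 1.0
        return acc.astype(float)
    col = cohort[term.predictor]
    if tr.type == "identity":
        return col.to_numpy(float)
    if tr.type == "per_units":
        return col.to_numpy(float) / tr.k
    if tr.type == "indicator":
        return (col.astype(str) == tr.level).to_numpy(float)
    if tr.type == "band":
        v = col.to_numpy(float)
        lo = -np.inf if tr.lo is None else tr.lo
        hi = np.inf if tr.hi is None else tr.hi
        return ((v >= lo) & (v < hi)).astype(float)
    raise AssertionError(tr.type)


def _require_complete(model: RiskModel, cohort: pd.DataFrame) -> None:
    needed = set()
    for t in model.active_terms:
        if t.transform.type == "any_of":
            needed.update(t.transform.predictors)
        else:
            needed.add(t.predictor)
    for p in sorted(needed):
        if cohort[p].isna().any():
            raise ValueError(
                f"predictor {p!r} has missing values; evaluate models on completed "
                "(post-imputation) data"
            )


def linear_predictor(model: RiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Sum of weight x transformed value over non-omitted terms."""
    if model.kind not in EQUATION_KINDS:
        raise ValueError(f"{model.name} is a {model.kind}, not an equation model")
    _require_complete(model, cohort)
    lp = np.zeros(len(cohort))
    for t in model.active_terms:
        lp += t.weight * _term_values(t, cohort)
    return lp


def sum_score(model: RiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Integer total points of the satisfied score-chart terms."""
    if model.kind != "score_chart":
        raise ValueError(f"{model.name} is a {model.kind}, not a score chart")
    _require_complete(model, cohort)
    score = np.zeros(len(cohort))
    for t in model.active_terms:
        score += t.points * _term_values(t, cohort)
    return score.astype(int)


def recalibrate_intercept(linear_predictors, outcomes) -> float:
    """Maximum-likelihood intercept of outcome ~ logistic(alpha + 1*LP).

    With the slope fixed at 1 the score equation reduces to: mean predicted
    probability equals the observed prevalence.  That one-dimensional,
    strictly monotone condition is solved by bracketed root finding to
    |mean(p) - prevalence| < 1e-10.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    prev = float(y.mean())
    if prev <= 0.0 or prev >= 1.0:
        raise ValueError("intercept is unbounded without both cases and non-cases")

    def f(a: float) -> float:
        return float(np.mean(expit(a + lp))) - prev

    return float(brentq(f, -60.0, 60.0, xtol=1e-12, rtol=8.9e-16))


def predicted_probability(alpha: float, lp) -> np.ndarray:
    """logistic(alpha + lp)."""
    return expit(alpha + np.asarray(lp, dtype=float))


def baseline_age_probability(age_threshold: float = 65.0) -> RiskModel:
    """The age-threshold comparator as a one-term equation model.

    An indicator of age >= threshold with unit weight; after intercept
    recalibration its two predicted risks are *not* the two stratum
    prevalences (a one-parameter fit cannot match both strata), so the
    reclassification module estimates the stratum prevalences directly
    instead of using this model.  Kept for AUROC comparisons, where only
    the ranking (old vs young) matters.
    """
    return RiskModel(
        name=f"age>={age_threshold:g}",
        kind="logistic_equation",
        terms=[
            PredictorTerm(
                predictor="age",
                transform=Transform(type="band", lo=age_threshold),
                weight=1.0,
            )
        ],
        source_citation="Age-threshold screening criterion",
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_model_definitions(paths=None) -> dict[str, RiskModel]:
    """Load and validate model definition files (JSON or YAML).

    With no arguments, loads the definitions bundled with the package:
    CHADS2, CHA2DS2-VASc, HATCH and C2HEST score charts and the CHARGE-AF
    equation.  Duplicate model names are rejected.
    """
    if paths is None:
        pkg = resources.files("afscreen.model_defs")
        docs = [
            json.loads(p.read_text(encoding="utf-8"))
            for p in sorted(pkg.iterdir(), key=lambda p: p.name)
            if p.name.endswith(".json")
        ]
    else:
        docs = []
        for path in paths:
            text = Path(path).read_text(encoding="utf-8")
            if str(path).endswith((".yaml", ".yml")):
                docs.append(yaml.safe_load(text))
            else:
                docs.append(json.loads(text))
    models: dict[str, RiskModel] = {}
    for doc in docs:
        model = RiskModel.model_validate(doc)
        if model.name in models:
            raise ValueError(f"duplicate model name {model.name!r}")
        models[model.name] = model
    return models


def logit_of(p: float) -> float:
    return float(logit(p))
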