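"""Synthetic screened-cohort generator.

Emulates the covariate structure of a large vascular-screening population —
marginal distributions, age/sex-linked comorbidity, a logistic AF outcome
with a controllable prevalence — plus pre-screening exclusion flags and
MCAR missingness, so the whole validation pipeline is exercisable without
the proprietary source data.  Defaults live in
:mod:`afscreen._cohort_constants`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import _cohort_constants as C
from . import dictionary as D

#: Columns that may never be masked by :func:`inject_missingness`.
_UNMASKABLE = frozenset({D.ID_COL, "age", "sex", D.OUTCOME, "bmi"} | set(D.FLAGS))

#: Hard upper bound on any per-variable missingness rate (beyond this the
#: variable would not be considered imputable downstream).
MAX_MISSING_RATE = 0.30


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort draw."""

    n: int = 100_000
    seed: int = 0
    target_prevalence: float = C.TARGET_PREVALENCE
    outcome_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(C.OUTCOME_COEFFICIENTS)
    )
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(C.MISSINGNESS_RATES)
    )
    exclusion_fractions: dict[str, float] = field(
        default_factory=lambda: dict(C.EXCLUSION_FRACTIONS)
    )

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        for k, v in self.outcome_coefficients.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite outcome coefficient for {k!r}")
        for k, v in self.missingness_rates.items():
            if not 0.0 <= v < MAX_MISSING_RATE:
                raise ValueError(
                    f"missingness rate for {k!r} must lie in [0, {MAX_MISSING_RATE})"
                )
        for k, v in self.exclusion_fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"exclusion fraction for {k!r} must lie in [0, 1]")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def solve_outcome_intercept(linear_predictors: np.ndarray, target_prevalence: float) -> float:
    """Intercept alpha with mean(expit(alpha + LP)) == target, to 1e-10.

    The mean predicted probability is strictly increasing in alpha, so a
    bracketed scalar root find suffices.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")

    def f(a: float) -> float:
        return float(np.mean(expit(a + lp))) - target_prevalence

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("target prevalence unreachable for these linear predictors")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw one raw synthetic cohort (before exclusions and BMI derivation).

    Deterministic for a fixed spec/seed.  The AF outcome is drawn from a
    logistic model on the covariates whose intercept is solved so the mean
    predicted probability equals ``spec.target_prevalence``; heart rate is
    then shifted upward in cases.  Exclusion flags are sampled independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5EED]))
    n = spec.n

    age = np.clip(rng.normal(C.AGE_MEAN, C.AGE_SD, n), *C.AGE_CLIP)
    female = rng.random(n) < C.FEMALE_FRACTION
    sex = np.where(female, "female", "male")

    cats = list(C.SMOKING_PROBS)
    probs = np.array([C.SMOKING_PROBS[c] for c in cats])
    smoking = rng.choice(cats, size=n, p=probs / probs.sum())

    height = np.empty(n)
    for s, (mu, sd) in C.HEIGHT_BY_SEX.items():
        m = sex == s
        height[m] = rng.normal(mu, sd, m.sum())
    height = np.clip(height, 1.2, 2.2)

    cv2 = (C.BMI_SD / C.BMI_MEAN) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(C.BMI_MEAN) - sigma**2 / 2.0
    bmi_draw = np.maximum(rng.lognormal(mu, sigma, n), C.BMI_MIN)
    weight = bmi_draw * height**2

    sbp = C.SBP_MEAN + C.SBP_AGE_SLOPE * (age - C.AGE_MEAN) + rng.normal(0, C.SBP_RESID_SD, n)
    sbp = np.maximum(sbp, 70.0)
    heart_rate = np.maximum(rng.normal(C.HR_MEAN, C.HR_SD, n), 35.0)

    age_dec = (age - 65.0) / 10.0
    male = (~female).astype(float)
    frailty = rng.standard_normal(n)
    histories: dict[str, np.ndarray] = {}
    for name, (target, b_age, b_male) in C.HISTORY_MODELS.items():
        lp_h = b_age * age_dec + b_male * male + C.FRAILTY_LOADING * frailty
        a = solve_outcome_intercept(lp_h, target)
        histories[name] = (rng.random(n) < expit(a + lp_h)).astype(float)

    co = spec.outcome_coefficients
    lp = (
        co.get("age_per_decade", 0.0) * age_dec
        + co.get("male", 0.0) * male
        + co.get("smoking_former", 0.0) * (smoking == "former")
        + co.get("smoking_current", 0.0) * (smoking == "current")
        + co.get("weight_per_kg", 0.0) * (weight - 79.1)
        + co.get("sbp_per_mmhg", 0.0) * (sbp - 133.0)
    )
    for name in C.HISTORY_MODELS:
        lp = lp + co.get(name, 0.0) * histories[name]

    alpha = solve_outcome_intercept(lp, spec.target_prevalence)
    af = (rng.random(n) < expit(alpha + lp)).astype(float)

    shift = rng.normal(C.HR_AF_SHIFT_MEAN, C.HR_AF_SHIFT_SD, n)
    heart_rate = np.where(af == 1.0, np.maximum(heart_rate + shift, 35.0), heart_rate)

    ex = spec.exclusion_fractions
    prior_af = (rng.random(n) < ex.get("prior_af_history", 0.0)).astype(float)
    no_ecg = rng.random(n) < ex.get("no_ecg", 0.0)
    sex_incons = rng.random(n) < ex.get("sex_inconsistent", 0.0)

    out = pd.DataFrame(
        {
            D.ID_COL: np.char.add("P", np.arange(1, n + 1).astype(str)),
            "age": np.round(age, 1),
            "sex": sex,
            "smoking": smoking,
            "height": np.round(height, 3),
            "weight": np.round(weight, 1),
            "bmi": np.nan,  # derived later, before imputation
            "sbp": np.round(sbp, 0),
            "heart_rate": np.round(heart_rate, 0),
            **{k: v for k, v in histories.items()},
            "prior_af_history": prior_af,
            "ecg_performed": (~no_ecg).astype(float),
            "sex_consistent": (~sex_incons).astype(float),
            D.OUTCOME: np.where(no_ecg, np.nan, af),
        }
    )
    return out[list(D.ALL_COLUMNS)]


def inject_missingness(
    cohort: pd.DataFrame, missingness_rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Mask cells missing-completely-at-random at per-variable rates.

    Identifier, age, sex, the AF outcome and the screening flags are never
    masked.  Rates at or above 0.30 are rejected: such a variable would not
    be imputable downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA5C]))
    out = cohort.copy()
    for col, rate in missingness_rates.items():
        if not 0.0 <= rate < MAX_MISSING_RATE:
            raise ValueError(
                f"missingness rate {rate} for {col!r} outside [0, {MAX_MISSING_RATE}): "
                "variables missing in 30% or more are not imputed"
            )
        if col in _UNMASKABLE:
            raise ValueError(f"column {col!r} may not be masked")
        if col not in out.columns:
            raise KeyError(f"unknown column {col!r}")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def logit_prevalence(p: float) -> float:
    """Convenience: logit of a prevalence (used for closed-form checks)."""
    return float(logit(p))
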