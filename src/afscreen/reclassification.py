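"""Reclassification of risk models against the age-threshold comparator.

The comparator "screen everyone aged >= 65" is turned into a two-valued
risk model by estimating the AF prevalence in the two age strata from the
analysis data.  Against it we compute:

* IDI — difference in discrimination slopes (mean predicted risk in cases
  minus non-cases) between model and comparator;
* rIDI — IDI divided by the comparator's discrimination slope;
* continuous NRI — net proportion of cases assigned a strictly higher risk
  by the model, plus net proportion of non-cases assigned a strictly lower
  risk (exact ties count as neither direction); bounded in [-2, 2].

Confidence intervals follow a nested bootstrap: B participant resamples
within each imputed dataset, all m*B statistic values pooled, the median
reported with the 2.5th/97.5th percentiles, and a two-sided p-value from
the pooled bootstrap distribution's tail proportion at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import dictionary as D
from .imputation import ImputedStack
from . import model_registry as registry

logger = logging.getLogger(__name__)


@dataclass
class ReclassStatistic:
    point: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ReclassResult:
    model: str
    idi: ReclassStatistic
    ridi: ReclassStatistic
    nri: ReclassStatistic
    b_replicates: int
    m_imputations: int
    seed: int
    p_value_method: str = "bootstrap tail proportion at 0"

    def to_dict(self) -> dict:
        return asdict(self)


def age_threshold_risks(cohort: pd.DataFrame, threshold: float = 65.0) -> np.ndarray:
    """Two-valued baseline risk: stratum prevalence above/below the age cut."""
    age = cohort["age"].to_numpy(float)
    y = cohort[D.OUTCOME].to_numpy(float)
    old = age >= threshold
    if old.all() or (~old).all():
        raise ValueError("age threshold does not split the cohort")
    risk_old = float(y[old].mean())
    risk_young = float(y[~old].mean())
    return np.where(old, risk_old, risk_young)


def discrimination_slope(predictions, outcomes) -> float:
    """Mean predicted risk among cases minus mean among non-cases."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    cases = y == 1
    if cases.all() or (~cases).all():
        raise ValueError("discrimination slope needs both cases and non-cases")
    return float(p[cases].mean() - p[~cases].mean())


def idi_ridi(model_predictions, baseline_predictions, outcomes) -> tuple[float, float]:
    """IDI and relative IDI of the model versus the baseline."""
    s_model = discrimination_slope(model_predictions, outcomes)
    s_base = discrimination_slope(baseline_predictions, outcomes)
    if s_base == 0.0:
        raise ValueError("baseline discrimination slope is zero; rIDI undefined")
    idi = s_model - s_base
    return idi, idi / s_base


def continuous_nri(model_predictions, baseline_predictions, outcomes) -> float:
    """Continuous (category-free) net reclassification improvement."""
    pm = np.asarray(model_predictions, dtype=float)
    pb = np.asarray(baseline_predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    cases = y == 1
    if cases.all() or (~cases).all():
        raise ValueError("NRI needs both cases and non-cases")
    up = pm > pb
    down = pm < pb
    nri_cases = up[cases].mean() - down[cases].mean()
    nri_noncases = down[~cases].mean() - up[~cases].mean()
    return float(nri_cases + nri_noncases)


def _percentile_summary(values: np.ndarray) -> ReclassStatistic:
    point = float(np.median(values))
    lo, hi = np.percentile(values, [2.5, 97.5])
    tail = 2.0 * min(float(np.mean(values <= 0.0)), float(np.mean(values >= 0.0)))
    return ReclassStatistic(
        point=point, ci_low=float(lo), ci_high=float(hi), p_value=min(tail, 1.0)
    )


def bootstrap_reclassification(
    stack: ImputedStack,
    model: registry.RiskModel,
    B: int = 1000,
    seed: int = 0,
    age_threshold: float = 65.0,
    model_probabilities: list[np.ndarray] | None = None,
) -> ReclassResult:
    """Nested bootstrap of IDI, rIDI and continuous NRI vs the age threshold.

    Within each imputed dataset the participants are resampled with
    replacement B times; IDI/rIDI/NRI are computed on every resample (risks
    and baseline prevalences are *not* re-estimated per resample — the
    point estimates condition on the fitted risks, as a plug-in bootstrap).
    The m*B values are pooled before taking the median and percentiles.
    Resamples that lose one outcome class are redrawn (an error after 100
    consecutive failures).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB001]))
    idis, ridis, nris = [], [], []
    for i, cp in enumerate(stack.copies):
        y = cp[D.OUTCOME].to_numpy(float)
        if model_probabilities is not None:
            pm = np.asarray(model_probabilities[i], dtype=float)
        else:
            lp = registry.linear_predictor(model, cp)
            alpha = registry.recalibrate_intercept(lp, y)
            pm = registry.predicted_probability(alpha, lp)
        pb = age_threshold_risks(cp, threshold=age_threshold)
        n = len(y)
        def _degenerate(idx: np.ndarray) -> bool:
            s = y[idx].sum()
            if s in (0, n):
                return True
            # a two-valued baseline can tie exactly on a resample; rIDI
            # would be undefined there
            return discrimination_slope(pb[idx], y[idx]) == 0.0

        drawn = 0
        while drawn < B:
            failures = 0
            idx = rng.integers(0, n, size=n)
            while _degenerate(idx):
                failures += 1
                logger.debug("degenerate resample redrawn (imputation %d)", i)
                if failures >= 100:
                    raise RuntimeError("100 consecutive degenerate bootstrap resamples")
                idx = rng.integers(0, n, size=n)
            yi, pmi, pbi = y[idx], pm[idx], pb[idx]
            idi, ridi = idi_ridi(pmi, pbi, yi)
            idis.append(idi)
            ridis.append(ridi)
            nris.append(continuous_nri(pmi, pbi, yi))
            drawn += 1
    return ReclassResult(
        model=model.name,
        idi=_percentile_summary(np.asarray(idis)),
        ridi=_percentile_summary(np.asarray(ridis)),
        nri=_percentile_summary(np.asarray(nris)),
        b_replicates=B,
        m_imputations=stack.m,
        seed=seed,
    )
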