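"""Discrimination and calibration of the risk models.

AUROC uses the Mann-Whitney estimator (ties count one half) with DeLong's
covariance machinery for standard errors and paired model comparisons.
Under multiple imputation the per-dataset AUROCs are pooled with Rubin's
rules on the natural scale; calibration works on the per-participant mean
predicted probability across imputations, split into deciles of predicted
risk with Wilson intervals around the observed prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from . import model_registry as registry
from .imputation import ImputedStack, PooledEstimate, pool_rubin


@dataclass
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(predictions: np.ndarray, outcomes: np.ndarray):
    """Per-observation structural components of the AUC (DeLong).

    Returns (auc, v10, v01): v10 over cases, v01 over non-cases.
    """
    pos = predictions[outcomes == 1]
    neg = predictions[outcomes == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUROC needs at least one case and one non-case")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def auroc(predictions, outcomes) -> RocResult:
    """Mann-Whitney AUROC with DeLong standard error and 95% normal CI."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    auc, v10, v01 = _delong_components(p, y)
    var = 0.0
    if len(v10) > 1:
        var += v10.var(ddof=1) / len(v10)
    if len(v01) > 1:
        var += v01.var(ddof=1) / len(v01)
    se = float(np.sqrt(var))
    half = 1.959963984540054 * se
    return RocResult(
        auc=float(auc),
        se=se,
        ci_low=max(0.0, float(auc - half)),
        ci_high=min(1.0, float(auc + half)),
    )


def compare_auroc(predictions_a, predictions_b, outcomes) -> tuple[float, float]:
    """Paired DeLong test; returns (auc_a - auc_b, two-sided p)."""
    a = np.asarray(predictions_a, dtype=float)
    b = np.asarray(predictions_b, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("prediction vectors must cover the same participants")
    auc_a, va10, va01 = _delong_components(a, y)
    auc_b, vb10, vb01 = _delong_components(b, y)
    m, n = len(va10), len(va01)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([va10, vb10]))
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([va01, vb01]))
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, 1.0 if delta == 0.0 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2.0 * stats.norm.sf(abs(z)))


def pool_auroc(
    stack: ImputedStack,
    model: registry.RiskModel,
    subset_masks: list[np.ndarray] | None = None,
) -> PooledEstimate:
    """AUROC per imputed dataset, combined with Rubin's rules.

    The AUROC is rank-based, so it is evaluated on the raw linear predictor
    or sum score; the recalibrated intercept cannot change it.
    """
    aucs, ses = [], []
    for i, cp in enumerate(stack.copies):
        if model.kind == "score_chart":
            pred = registry.sum_score(model, cp)
        else:
            pred = registry.linear_predictor(model, cp)
        y = cp[_outcome_col()].to_numpy(float)
        if subset_masks is not None:
            keep = np.asarray(subset_masks[i], dtype=bool)
            pred, y = pred[keep], y[keep]
        roc = auroc(pred, y)
        aucs.append(roc.auc)
        ses.append(roc.se)
    pooled = pool_rubin(aucs, ses)
    return pooled


def _outcome_col() -> str:
    from . import dictionary as D

    return D.OUTCOME


def calibration_deciles(mean_predictions, outcomes) -> pd.DataFrame:
    """Decile calibration table of observed vs mean predicted risk.

    Participants are ranked by mean predicted probability (stable order on
    ties) and cut into 10 near-equal bins; per bin: n, mean predicted risk,
    observed cases, observed prevalence with a Wilson 95% interval.
    """
    p = np.asarray(mean_predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(p)
    if n < 10:
        raise ValueError("decile calibration needs at least 10 participants")
    order = np.argsort(p, kind="stable")
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = (np.arange(n) * 10) // n
    rows = []
    for b in range(10):
        sel = bin_of == b
        nb = int(sel.sum())
        cases = int(y[sel].sum())
        prev = cases / nb
        lo, hi = proportion_confint(cases, nb, alpha=0.05, method="wilson")
        rows.append(
            {
                "decile": b + 1,
                "n": nb,
                "mean_predicted": float(p[sel].mean()),
                "observed_cases": cases,
                "observed_prevalence": prev,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def prevalence_by_sum_score(scores, outcomes) -> pd.DataFrame:
    """Observed AF prevalence at each realised sum score (Wilson 95% CI)."""
    s = np.asarray(scores, dtype=int)
    y = np.asarray(outcomes, dtype=float)
    rows = []
    for val in np.unique(s):
        sel = s == val
        nb = int(sel.sum())
        cases = int(y[sel].sum())
        lo, hi = proportion_confint(cases, nb, alpha=0.05, method="wilson")
        rows.append(
            {
                "score": int(val),
                "n": nb,
                "observed_cases": cases,
                "observed_prevalence": cases / nb,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def mean_probability_across_imputations(
    stack: ImputedStack, model: registry.RiskModel
) -> np.ndarray:
    """Per-participant mean recalibrated probability across the m copies.

    Each copy gets its own calibration-in-the-large intercept, so the mean
    over participants of the returned vector equals the cohort prevalence
    exactly (each copy satisfies the score equation, and the outcome is
    identical across copies).
    """
    if model.kind == "score_chart":
        raise ValueError("score charts have no probability scale; use sum scores")
    acc = None
    for cp in stack.copies:
        lp = registry.linear_predictor(model, cp)
        y = cp[_outcome_col()].to_numpy(float)
        alpha = registry.recalibrate_intercept(lp, y)
        prob = registry.predicted_probability(alpha, lp)
        acc = prob if acc is None else acc + prob
    return acc / stack.m


def mean_score_across_imputations(stack: ImputedStack, model: registry.RiskModel) -> np.ndarray:
    """Across-imputation mean sum score, rounded half-up to an integer."""
    acc = None
    for cp in stack.copies:
        s = registry.sum_score(model, cp).astype(float)
        acc = s if acc is None else acc + s
    return np.floor(acc / stack.m + 0.5).astype(int)
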