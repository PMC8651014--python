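"""Multiple imputation by chained equations, range rounding, Rubin pooling.

The chained-equation sampler is deliberately transparent rather than clever:

* continuous variables (height, weight, SBP, heart rate) are imputed from a
  Bayesian normal linear regression on all other variables — the residual
  variance is drawn from its scaled inverse-chi-square posterior and the
  coefficients from their conditional normal, so repeated imputations carry
  genuine between-imputation variability;
* binary histories are imputed from a logistic regression, drawing the
  missing cells as Bernoulli at the fitted probabilities;
* smoking status is imputed from a multinomial logistic regression.

The AF outcome enters every conditional model as a predictor but is never
itself imputed.  BMI is not part of the chain: it is recomputed from the
completed height and weight of each copy, keeping the three mutually
consistent.  Variables missing in 30% or more of records are refused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from . import dictionary as D

logger = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.30

#: Plausible physiologic ranges used for post-imputation rounding.
DEFAULT_RANGE_LIMITS: dict[str, tuple[float, float]] = {
    "sbp": (60.0, 260.0),
    "heart_rate": (30.0, 220.0),
    "height": (1.2, 2.2),
    "weight": (30.0, 250.0),
    "bmi": (14.0, 70.0),
}

_CONTINUOUS = ("height", "weight", "sbp", "heart_rate")
_BINARY = set(D.BINARY_HISTORIES)


@dataclass
class ImputationConfig:
    """Knobs of the chained-equation sampler.

    The defaults (m=20 datasets, 200 sweeps) mirror a full production run;
    analyses on large cohorts routinely scale these down — results carry the
    config snapshot so the run size is always explicit.
    """

    m: int = 20
    iterations: int = 200
    seed: int = 0
    range_limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGE_LIMITS)
    )

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for col, (lo, hi) in self.range_limits.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad range limits for {col!r}: ({lo}, {hi})")


@dataclass
class ImputedStack:
    """m completed copies of the analysis cohort plus provenance."""

    copies: list[pd.DataFrame]
    missing_mask: pd.DataFrame  # True where the input cell was missing
    config: ImputationConfig

    @property
    def m(self) -> int:
        return len(self.copies)

    def __iter__(self):
        return iter(self.copies)

    def __getitem__(self, i: int) -> pd.DataFrame:
        return self.copies[i]


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates."""

    point: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_rubin(estimates, standard_errors, alpha: float = 0.05) -> PooledEstimate:
    """Pool m (estimate, SE) pairs.

    Q-bar is the mean estimate; W the mean squared SE; B the sample variance
    of the estimates; T = W + (1 + 1/m) B.  The interval uses a t quantile
    with df = (m-1) * (1 + W / ((1+1/m) B))^2, degenerating to the normal
    quantile when B = 0 (including the m = 1 case).
    """
    q = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if q.size == 0:
        raise ValueError("need at least one estimate")
    if q.shape != se.shape:
        raise ValueError("estimates and standard errors must align")
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    m = q.size
    point = float(q.mean())
    w = float(np.mean(se**2))
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t_var = w + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    else:
        df = float("inf")
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = crit * float(np.sqrt(t_var))
    return PooledEstimate(
        point=point,
        within_variance=w,
        between_variance=b,
        total_variance=t_var,
        df=df,
        ci_low=point - half,
        ci_high=point + half,
    )


# ---------------------------------------------------------------------------
# chained-equation machinery
# ---------------------------------------------------------------------------


def _design_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric design matrix from all variables except ``exclude`` (+ intercept)."""
    cols = [np.ones(len(df))]
    if exclude != "age":
        cols.append(df["age"].to_numpy(float))
    cols.append((df["sex"] == "male").to_numpy(float))
    if exclude != "smoking":
        cols.append((df["smoking"] == "former").to_numpy(float))
        cols.append((df["smoking"] == "current").to_numpy(float))
    for c in _CONTINUOUS:
        if c != exclude:
            cols.append(df[c].to_numpy(float))
    for c in D.BINARY_HISTORIES:
        if c != exclude:
            cols.append(df[c].to_numpy(float))
    cols.append(df[D.OUTCOME].to_numpy(float))
    return np.column_stack(cols)


def _draw_continuous(X, y, obs, rng) -> np.ndarray:
    """Posterior-predictive draw for the missing cells of one continuous var."""
    Xo, yo = X[obs], y[obs]
    n, p = Xo.shape
    xtx = Xo.T @ Xo + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(xtx, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = np.linalg.inv(xtx)
    beta = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(p) * np.sqrt(sigma2)
    Xm = X[~obs]
    return Xm @ beta + rng.standard_normal(len(Xm)) * np.sqrt(sigma2)


#: Cap on rows used to fit one conditional model (the fit subsample is a
#: fresh seeded draw each sweep; prediction always covers every missing cell).
_MAX_FIT_ROWS = 20_000


def _draw_categorical(X, y_codes, obs, rng) -> np.ndarray:
    """Draw class codes for missing cells from a fitted (multinomial) logit.

    Features are standardised to the observed scale before fitting; a
    degenerate single-class conditional imputes that class outright.
    """
    yo = y_codes[obs]
    present = np.unique(yo)
    if present.size == 1:
        return np.full(int((~obs).sum()), present[0])
    Z = X[:, 1:]  # sklearn adds its own intercept
    mu = Z[obs].mean(axis=0)
    sd = Z[obs].std(axis=0)
    sd[sd == 0] = 1.0
    Zs = (Z - mu) / sd
    fit_idx = np.flatnonzero(obs)
    if fit_idx.size > _MAX_FIT_ROWS:
        fit_idx = rng.choice(fit_idx, size=_MAX_FIT_ROWS, replace=False)
        if np.unique(y_codes[fit_idx]).size == 1:
            return np.full(int((~obs).sum()), y_codes[fit_idx][0])
    clf = LogisticRegression(C=1e4, solver="newton-cholesky", max_iter=100)
    clf.fit(Zs[fit_idx], y_codes[fit_idx])
    prob = clf.predict_proba(Zs[~obs])
    cum = prob.cumsum(axis=1)
    u = rng.random(len(prob))[:, None]
    idx = (u > cum).sum(axis=1)
    return clf.classes_[np.minimum(idx, prob.shape[1] - 1)]


def impute_chained(cohort: pd.DataFrame, config: ImputationConfig) -> ImputedStack:
    """Run chained-equation imputation, returning m completed copies.

    Missing cells are initialised by random draws from the observed marginal
    of their variable, then the sampler cycles variables in ascending order
    of missingness fraction for ``config.iterations`` sweeps per copy.
    Deterministic for a fixed config seed.
    """
    df = cohort.reset_index(drop=True)
    for col in ("age", "sex", D.OUTCOME):
        if df[col].isna().any():
            raise ValueError(f"{col!r} may not be missing in the analysis cohort")

    imputable = [c for c in _CONTINUOUS if df[c].isna().any()]
    imputable += [c for c in D.BINARY_HISTORIES if df[c].isna().any()]
    if df["smoking"].isna().any():
        imputable.append("smoking")
    fracs = {c: float(df[c].isna().mean()) for c in imputable}
    too_high = [c for c, f in fracs.items() if f >= MAX_MISSING_FRACTION]
    if too_high:
        raise ValueError(
            f"variable(s) {too_high} missing in >= {MAX_MISSING_FRACTION:.0%}; not imputable"
        )
    order = sorted(imputable, key=lambda c: (fracs[c], list(df.columns).index(c)))

    mask = df.isna()
    mask[D.OUTCOME] = False
    smoking_levels = np.array(D.CATEGORICAL["smoking"])

    root = np.random.SeedSequence([int(config.seed), 0x1CE])
    copies: list[pd.DataFrame] = []
    for chain_seq in root.spawn(config.m):
        rng = np.random.default_rng(chain_seq)
        work = df.copy()
        if not order:
            copies.append(_finalise(work, mask, config))
            continue
        # initialise from observed marginals
        for col in order:
            mis = mask[col].to_numpy()
            obs_vals = work.loc[~mask[col], col].to_numpy()
            work.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()), replace=True)
        for sweep in range(config.iterations):
            for col in order:
                mis = mask[col].to_numpy()
                X = _design_matrix(work, exclude=col)
                if not np.all(np.isfinite(X)):
                    raise RuntimeError(
                        f"non-finite design while imputing {col!r} at sweep {sweep}"
                    )
                if col in _BINARY:
                    codes = work[col].to_numpy(float).astype(int)
                    drawn = _draw_categorical(X, codes, ~mis, rng)
                    work.loc[mis, col] = drawn.astype(float)
                elif col == "smoking":
                    codes = np.searchsorted(smoking_levels, work[col].to_numpy(str))
                    drawn = _draw_categorical(X, codes, ~mis, rng)
                    work.loc[mis, col] = smoking_levels[drawn]
                else:
                    y = work[col].to_numpy(float)
                    work.loc[mis, col] = _draw_continuous(X, y, ~mis, rng)
        copies.append(_finalise(work, mask, config))

    return ImputedStack(copies=copies, missing_mask=mask, config=config)


def _finalise(work: pd.DataFrame, mask: pd.DataFrame, config: ImputationConfig) -> pd.DataFrame:
    """Clamp imputed cells to range limits and recompute BMI."""
    out = work.copy()
    for col, (lo, hi) in config.range_limits.items():
        if col == "bmi" or col not in out.columns:
            continue
        imputed = mask[col].to_numpy()
        out.loc[imputed, col] = out.loc[imputed, col].clip(lo, hi)
    out["bmi"] = out["weight"] / out["height"] ** 2
    if "bmi" in config.range_limits:
        lo, hi = config.range_limits["bmi"]
        derived = (mask["height"] | mask["weight"]).to_numpy()
        out.loc[derived, "bmi"] = out.loc[derived, "bmi"].clip(lo, hi)
    return out


def apply_range_rounding(
    stack: ImputedStack, range_limits: dict[str, tuple[float, float]] | None = None
) -> ImputedStack:
    """Clamp *imputed* cells of limited-range variables to their bounds.

    Observed cells are never touched; applying the operation twice is a
    no-op.  (``impute_chained`` already applies the config's limits; this
    entry point exists to re-round a stack under different limits.)
    """
    limits = dict(range_limits or stack.config.range_limits)
    copies = []
    for cp in stack.copies:
        out = cp.copy()
        for col, (lo, hi) in limits.items():
            if col not in out.columns:
                continue
            if col == "bmi":
                imputed = (stack.missing_mask["height"] | stack.missing_mask["weight"]).to_numpy()
            else:
                imputed = stack.missing_mask[col].to_numpy()
            out.loc[imputed, col] = out.loc[imputed, col].clip(lo, hi)
        copies.append(out)
    return ImputedStack(copies=copies, missing_mask=stack.missing_mask, config=stack.config)
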