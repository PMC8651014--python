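"""Selective-screening test characteristics at top-risk fractions.

Screening the fraction ``q`` of participants with the highest predicted
risk yields a 2x2 table of selection x AF, from which sensitivity,
specificity, predictive values, in-screen prevalence and the number needed
to screen (NNS) follow.  NNS is the ceiling of 1/PPV — a programme cannot
screen a fraction of a person.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class ScreeningResult:
    q: float
    threshold: float          # lowest predicted risk among the screened
    n_screened: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence_in_screened: float
    nns: int

    def to_dict(self) -> dict:
        return asdict(self)


def metrics_at_top_fraction(mean_predictions, outcomes, q: float) -> ScreeningResult:
    """Test characteristics of screening the ceil(q*n) highest-risk people.

    Ties at the selection boundary are broken by stable participant order.
    Requires at least one case (sensitivity is undefined otherwise).
    """
    p = np.asarray(mean_predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    n = len(p)
    total_cases = int(y.sum())
    if total_cases == 0:
        raise ValueError("sensitivity undefined: no cases in the cohort")
    k = math.ceil(q * n)
    # stable: among tied risks, earlier participants are selected first
    order = np.argsort(-p, kind="stable")
    screened = np.zeros(n, dtype=bool)
    screened[order[:k]] = True
    tp = int(y[screened].sum())
    fp = k - tp
    fn = total_cases - tp
    tn = n - k - fn
    ppv = tp / k
    return ScreeningResult(
        q=float(q),
        threshold=float(p[order[k - 1]]),
        n_screened=k,
        sensitivity=tp / total_cases,
        specificity=tn / (tn + fp) if (tn + fp) else 0.0,
        ppv=ppv,
        npv=tn / (tn + fn) if (tn + fn) else float("nan"),
        prevalence_in_screened=ppv,
        nns=math.ceil(1.0 / ppv) if ppv > 0 else int(1e12),
    )


def metrics_curve(mean_predictions, outcomes, q_grid) -> list[ScreeningResult]:
    """One :class:`ScreeningResult` per fraction in ``q_grid``."""
    return [metrics_at_top_fraction(mean_predictions, outcomes, q) for q in q_grid]
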