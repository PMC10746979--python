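"""Construct validity: odds of adverse health outcomes among screen positives.

A screening test for sarcopenia should flag people who carry the adverse
correlates of the disease.  This module quantifies that with odds ratios:
unadjusted from a 2x2 exposure table, and adjusted (age, sex, BMI) from a
logistic regression.  Tests are one-tailed (H1: OR > 1 — screen positives
have *more* adverse outcomes) while CIs remain conventional two-sided 95%.

By default the regression models the risk factor as the outcome and
index-test status as the predictor ("screen positives have higher odds of
the factor"); the reverse direction is available via ``outcome=``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .classifier import _firth_logistic, SeparationWarning

__all__ = ["ExposureTable", "OddsRatioResult", "unadjusted_or", "adjusted_or"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureTable:
    """2x2 exposure table: a/b = exposed case/non-case, c/d = unexposed.

    "Case" is an app-positive (index-test sarcopenic) participant; "exposed"
    means the risk factor is present.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("empty exposure table")


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_one_tailed: float
    corrected: bool = False  # Haldane-Anscombe 0.5 added to zero cells
    method: str = "woolf"

    def to_dict(self) -> dict:
        return {
            "or": self.odds_ratio,
            "ci95": [self.ci_low, self.ci_high],
            "p_one_tailed": self.p_one_tailed,
            "corrected": self.corrected,
            "method": self.method,
        }


def unadjusted_or(table: ExposureTable, level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio ad/bc with a Woolf (log-method) CI.

    Any zero cell triggers the Haldane–Anscombe correction (+0.5 to every
    cell, flagged in the result).  The one-tailed p tests OR > 1 via the
    Wald z on the log scale.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        logger.info("zero cell in exposure table %s: Haldane-Anscombe 0.5 applied", (a, b, c, d))
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    zstat = math.log(orr) / se
    return OddsRatioResult(
        odds_ratio=float(orr),
        ci_low=float(orr * math.exp(-z * se)),
        ci_high=float(orr * math.exp(z * se)),
        p_one_tailed=float(stats.norm.sf(zstat)),
        corrected=corrected,
    )


def adjusted_or(
    data: pd.DataFrame,
    factor: str,
    label_col: str = "app_sarcopenia",
    covariates: tuple[str, ...] = ("age_years", "sex", "bmi"),
    outcome: str = "factor",
    level: float = 0.95,
) -> OddsRatioResult:
    """Covariate-adjusted odds ratio from a logistic regression.

    ``outcome="factor"`` (default) regresses the risk factor on index-test
    status plus covariates; ``outcome="sarcopenia"`` reverses the direction.
    ``sex`` is dummy-coded (male = 1).  Constant covariate columns are
    dropped with a warning; separation falls back to a Firth fit.
    """
    if outcome == "factor":
        ycol, xcol = factor, label_col
    elif outcome == "sarcopenia":
        ycol, xcol = label_col, factor
    else:
        raise ValueError(f"outcome must be 'factor' or 'sarcopenia', got {outcome!r}")
    cols = [ycol, xcol, *covariates]
    sub = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    missing = [c for c in cols if c not in sub.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    y = sub[ycol].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {ycol!r} is single-class")

    design = {"predictor": sub[xcol].astype(float).to_numpy()}
    for cov in covariates:
        v = sub[cov]
        if v.dtype == object or cov == "sex":
            v = (v == "male").astype(float) if v.dtype == object else v.astype(float)
        v = v.astype(float).to_numpy()
        if np.ptp(v) == 0:
            warnings.warn(
                f"covariate {cov!r} is constant and was dropped from the adjustment",
                UserWarning,
                stacklevel=2,
            )
            continue
        design[cov] = v
    X = sm.add_constant(np.column_stack(list(design.values())))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = res.params, res.bse
        if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 1e4:
            raise ValueError("degenerate MLE")
        method = "mle"
    except Exception:
        warnings.warn(
            "separation in the adjusted model; Firth penalized fit used",
            SeparationWarning,
            stacklevel=2,
        )
        params, cov_ = _firth_logistic(X, y)
        bse = np.sqrt(np.diag(cov_))
        method = "firth"
    beta, se = float(params[1]), float(bse[1])  # the predictor of interest
    z = stats.norm.ppf(0.5 + level / 2)
    return OddsRatioResult(
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_one_tailed=float(stats.norm.sf(beta / se)),
        method=f"logistic-{method}",
    )
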