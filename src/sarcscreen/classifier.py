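"""The index test: sex-stratified logistic screening models.

Sarcopenia status is modelled, separately per sex and per reference-standard
criterion, as a logistic function of two predictors measurable without a
dynamometer or body-composition device: vertical power from the chair rise
(W/kg) and calf circumference (meters):

    p = 1 / (1 + exp(-z)),   z = b0 + b_power * power + b_calf * calf

A participant is classified sarcopenic when p >= cutoff, with the cutoff
chosen on the ROC of predicted probabilities (Youden's J by default).
Model quality is assessed by Hosmer–Lemeshow calibration and Harrell's
bootstrap optimism correction of the c-statistic.

Maximum-likelihood fitting is delegated to statsmodels; complete or quasi-
complete separation (common in tiny cohorts with rare events) falls back to
Jeffreys-prior (Firth) penalized likelihood with a warning.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .accuracy import auc_mann_whitney
from .ewgsop2 import SarcopeniaCriterion

__all__ = [
    "LogisticSarcopeniaModel",
    "FitDiagnostics",
    "UnfittableError",
    "NoDiscriminationError",
    "SeparationWarning",
    "fit_model",
    "predict_probability",
    "select_cutoff",
    "hosmer_lemeshow",
    "bootstrap_optimism",
    "classify",
    "load_model_json",
    "save_model_json",
]

logger = logging.getLogger(__name__)

#: Default bootstrap seed (arbitrary; any analysis should set its own).
DEFAULT_SEED = 20220201

_Z_CLAMP = 700.0  # exp overflow guard


class UnfittableError(ValueError):
    """The cohort cannot support a logistic fit (e.g. a single outcome class)."""


class NoDiscriminationError(ValueError):
    """All predicted probabilities are identical; no cutoff can discriminate."""


class SeparationWarning(UserWarning):
    """Perfect separation detected; a penalized fit was used instead."""


@dataclass
class LogisticSarcopeniaModel:
    """Sex- and criterion-specific coefficients plus an optional cutoff.

    ``b_calf`` is per meter of calf circumference.  ``cutoff_probability`` is
    set by :func:`select_cutoff` (or loaded from config); classification is
    positive when predicted probability >= cutoff.
    """

    sex: str
    criterion: SarcopeniaCriterion
    b0: float
    b_power: float
    b_calf: float
    cutoff_probability: float | None = None
    standard_errors: dict[str, float] | None = None
    method: str = "mle"  # "mle" or "firth"
    converged: bool = True
    n_fit: int | None = None

    def __post_init__(self) -> None:
        if self.cutoff_probability is not None and not 0 < self.cutoff_probability < 1:
            raise ValueError(
                f"cutoff_probability must lie in (0, 1), got {self.cutoff_probability}"
            )

    def linear_predictor(self, power, calf):
        return self.b0 + self.b_power * np.asarray(power, float) + self.b_calf * np.asarray(calf, float)


def predict_probability(model: LogisticSarcopeniaModel, power, calf):
    """Predicted sarcopenia probability; scalar in, scalar out."""
    z = np.clip(model.linear_predictor(power, calf), -_Z_CLAMP, _Z_CLAMP)
    p = expit(z)
    return float(p) if np.ndim(p) == 0 else p


def classify(model: LogisticSarcopeniaModel, power, calf):
    """Index-test label: 1 (sarcopenic) iff p >= cutoff, else 0 (healthy).

    The boundary p == cutoff is positive, so the selected operating point
    reproduces the sensitivity seen in the ROC scan.
    """
    if model.cutoff_probability is None:
        raise ValueError("model has no cutoff_probability; run select_cutoff first")
    p = predict_probability(model, power, calf)
    out = np.asarray(p) >= model.cutoff_probability
    return int(out) if np.ndim(out) == 0 else out.astype(int)


# -- fitting -----------------------------------------------------------------


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Jeffreys-prior penalized logistic regression (Firth's bias reduction).

    Newton–Raphson on the modified score U*(b) = X'(y - p + h (1/2 - p)) with
    h the leverages of the weighted design.  Finite estimates exist even
    under complete separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_Z_CLAMP, _Z_CLAMP)
        p = expit(eta)
        w = p * (1 - p)
        info = (X * w[:, None]).T @ X
        info_inv = np.linalg.pinv(info)
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # halve the step until the penalized log-likelihood is non-decreasing
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.pinv(info)
    return beta, cov


def fit_model(
    cohort: pd.DataFrame,
    sex: str,
    criterion: SarcopeniaCriterion | str,
    power_col: str = "power_wkg",
    calf_col: str = "calf_circumference_m",
    label_col: str | None = None,
) -> LogisticSarcopeniaModel:
    """Maximum-likelihood logistic fit of sarcopenia on (power, calf).

    *cohort* must carry the power and calf columns plus a binary label column
    (default ``sarc_<criterion>``).  Rows of other sexes or with missing
    values are dropped.  Requires at least 10 usable rows and both classes.
    """
    criterion = (
        SarcopeniaCriterion.parse(criterion) if isinstance(criterion, str) else criterion
    )
    label_col = label_col or f"sarc_{criterion.label}"
    sub = cohort
    if "sex" in cohort.columns:
        sub = sub[sub["sex"] == sex]
    cols = [power_col, calf_col, label_col]
    sub = sub.dropna(subset=cols)
    n = len(sub)
    if n < 10:
        raise UnfittableError(f"need >= 10 usable rows, got {n}")
    y = sub[label_col].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise UnfittableError(
            f"labels are single-class ({'all positive' if y.any() else 'all negative'})"
        )
    X = sm.add_constant(sub[[power_col, calf_col]].astype(float).to_numpy())

    params = bse = None
    converged = True
    method = "mle"
    try:
        with warnings.catch_warnings():
            # separation/convergence chatter is handled by the post-fit check;
            # numeric overflow is escalated so the fallback engages
            warnings.simplefilter("ignore")
            warnings.filterwarnings("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = res.params, res.bse
        converged = bool(res.mle_retvals.get("converged", True))
        if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 1e4:
            raise ValueError("degenerate MLE")
    except Exception:
        params = None
    if params is None or not converged:
        warnings.warn(
            "perfect separation or non-convergence in the ML fit; using "
            "Jeffreys-prior penalized (Firth) logistic regression",
            SeparationWarning,
            stacklevel=2,
        )
        params, cov = _firth_logistic(X, y)
        bse = np.sqrt(np.diag(cov))
        method = "firth"
        converged = True
    return LogisticSarcopeniaModel(
        sex=sex,
        criterion=criterion,
        b0=float(params[0]),
        b_power=float(params[1]),
        b_calf=float(params[2]),
        standard_errors={
            "b0": float(bse[0]),
            "b_power": float(bse[1]),
            "b_calf": float(bse[2]),
        },
        method=method,
        converged=converged,
        n_fit=n,
    )


# -- ROC cutoff --------------------------------------------------------------


def _operating_point(probs: np.ndarray, y: np.ndarray, cutoff: float):
    pos = probs >= cutoff
    tp = int((pos & (y == 1)).sum())
    fn = int((~pos & (y == 1)).sum())
    fp = int((pos & (y == 0)).sum())
    tn = int((~pos & (y == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec


def select_cutoff(
    model: LogisticSarcopeniaModel,
    cohort: pd.DataFrame,
    power_col: str = "power_wkg",
    calf_col: str = "calf_circumference_m",
    label_col: str | None = None,
    rule: str = "youden",
) -> float:
    """Best probability cutoff from an ROC scan of predicted probabilities.

    Candidate cutoffs are the midpoints between consecutive distinct
    predicted probabilities plus the 0/1 sentinels.  ``rule`` selects the
    optimality criterion: ``youden`` (maximize J = sens + spec - 1, ties
    toward higher sensitivity), ``closest-topleft`` (minimize distance to the
    (0, 1) ROC corner), or ``fixed-sensitivity:<s>`` (lowest-specificity-cost
    cutoff with sens >= s).
    """
    label_col = label_col or f"sarc_{model.criterion.label}"
    sub = cohort
    if "sex" in cohort.columns:
        sub = sub[sub["sex"] == model.sex]
    sub = sub.dropna(subset=[power_col, calf_col, label_col])
    y = sub[label_col].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise UnfittableError("cutoff selection needs both classes present")
    probs = predict_probability(model, sub[power_col].to_numpy(), sub[calf_col].to_numpy())
    probs = np.atleast_1d(probs)
    uniq = np.unique(probs)
    if uniq.size == 1:
        raise NoDiscriminationError("all predicted probabilities identical")
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]))

    best_cut, best_key = None, None
    for c in candidates:
        sens, spec = _operating_point(probs, y, c)
        if rule == "youden":
            key = (sens + spec - 1, sens, -c)
        elif rule == "closest-topleft":
            key = (-math.hypot(1 - sens, 1 - spec), sens, -c)
        elif rule.startswith("fixed-sensitivity:"):
            target = float(rule.split(":", 1)[1])
            key = (sens >= target, spec, -c)
        else:
            raise ValueError(f"unknown cutoff rule {rule!r}")
        if best_key is None or key > best_key:
            best_key, best_cut = key, float(c)
    sens, spec = _operating_point(probs, y, best_cut)
    if sens + spec - 1 < 0.05:
        warnings.warn(
            f"selected cutoff has Youden J = {sens + spec - 1:.3f}: the model "
            "barely discriminates on these data",
            UserWarning,
            stacklevel=2,
        )
    return best_cut


# -- calibration -------------------------------------------------------------


def hosmer_lemeshow(probs, y, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit by deciles of risk.

    Sorts by predicted probability, splits into *groups* near-equal bins,
    and compares observed with expected events: chi-square with
    ``groups - 2`` degrees of freedom.  Bins with a vanishing expected count
    are merged into their neighbor (logged).
    """
    if groups < 3:
        raise ValueError(f"groups={groups} leaves no degrees of freedom (df = groups - 2)")
    p = np.asarray(probs, dtype=float)
    yy = np.asarray(y, dtype=float)
    if p.shape != yy.shape:
        raise ValueError("probs and y must be aligned")
    if p.size < 10 * groups:
        warnings.warn(
            f"n={p.size} < 10*groups; the chi-square approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    order = np.argsort(p, kind="mergesort")
    bins = np.array_split(order, groups)
    rows = []
    for b in bins:
        if len(b) == 0:
            continue
        rows.append((yy[b].sum(), p[b].sum(), len(b)))
    # merge bins whose expected events or non-events vanish
    merged = []
    for row in rows:
        o1, e1, m = row
        if merged and (e1 < 1e-9 or (m - e1) < 1e-9):
            po1, pe1, pm = merged[-1]
            merged[-1] = (po1 + o1, pe1 + e1, pm + m)
            logger.info("Hosmer-Lemeshow: merged a zero-expected bin into its neighbor")
        else:
            merged.append(row)
    if len(merged) < 3:
        raise ValueError("too few usable risk groups after merging")
    stat = 0.0
    for o1, e1, m in merged:
        stat += (o1 - e1) ** 2 / e1 + ((m - o1) - (m - e1)) ** 2 / (m - e1)
    df = len(merged) - 2
    pval = float(stats.chi2.sf(stat, df))
    return float(stat), df, pval


# -- internal validation -----------------------------------------------------


@dataclass
class FitDiagnostics:
    """Apparent and optimism-corrected discrimination plus calibration."""

    apparent_c: float
    optimism: float
    corrected_c: float
    hl_statistic: float | None = None
    hl_df: int | None = None
    hl_pvalue: float | None = None
    n_bootstrap: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not (self.corrected_c <= self.apparent_c + 1e-9 or self.optimism < 0):
            raise ValueError("corrected c must not exceed apparent c")


def bootstrap_optimism(
    model: LogisticSarcopeniaModel,
    cohort: pd.DataFrame,
    B: int = 1000,
    seed: int = DEFAULT_SEED,
    power_col: str = "power_wkg",
    calf_col: str = "calf_circumference_m",
    label_col: str | None = None,
) -> FitDiagnostics:
    """Harrell bootstrap optimism correction of the c-statistic.

    For each of *B* resamples (with replacement, same n): refit, evaluate the
    refit on the resample and on the original data; the mean difference is
    the optimism, subtracted from the apparent c.  Resamples that lose one
    outcome class are skipped and counted.  Bit-reproducible given *seed*.
    """
    if B <= 0:
        raise ValueError(f"B must be positive, got {B}")
    label_col = label_col or f"sarc_{model.criterion.label}"
    sub = cohort
    if "sex" in cohort.columns:
        sub = sub[sub["sex"] == model.sex]
    sub = sub.dropna(subset=[power_col, calf_col, label_col]).reset_index(drop=True)
    y = sub[label_col].astype(int).to_numpy()
    power = sub[power_col].to_numpy(float)
    calf = sub[calf_col].to_numpy(float)
    n = len(sub)

    p_orig = predict_probability(model, power, calf)
    apparent_c, _ = auc_mann_whitney(p_orig, y)
    hl_stat, hl_df, hl_p = hosmer_lemeshow(np.atleast_1d(p_orig), y)

    rng = np.random.default_rng(seed)
    optimisms = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped += 1
            continue
        boot = sub.iloc[idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mb = fit_model(
                    boot, model.sex, model.criterion,
                    power_col=power_col, calf_col=calf_col, label_col=label_col,
                )
        except UnfittableError:
            skipped += 1
            continue
        c_boot, _ = auc_mann_whitney(
            predict_probability(mb, power[idx], calf[idx]), yb
        )
        c_test, _ = auc_mann_whitney(predict_probability(mb, power, calf), y)
        optimisms.append(c_boot - c_test)
    if skipped:
        logger.info("bootstrap_optimism: skipped %d of %d resamples (single class)", skipped, B)
    if not optimisms:
        raise UnfittableError("every bootstrap resample was degenerate")
    optimism = float(np.mean(optimisms))
    return FitDiagnostics(
        apparent_c=float(apparent_c),
        optimism=optimism,
        corrected_c=float(apparent_c - optimism),
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_pvalue=hl_p,
        n_bootstrap=len(optimisms),
        n_skipped=skipped,
    )


# -- model config I/O --------------------------------------------------------


def save_model_json(model: LogisticSarcopeniaModel, path) -> None:
    """Serialize a model to JSON (calf coefficient stored per meter)."""
    d = asdict(model)
    d["criterion"] = model.criterion.label
    d["calf_units"] = "m"
    Path(path).write_text(json.dumps(d, indent=2))


def load_model_json(path) -> LogisticSarcopeniaModel:
    """Load a model config; a ``calf_units: cm`` declaration rescales ``b_calf``.

    A coefficient quoted per centimeter of calf corresponds to 100x the
    per-meter coefficient used internally.
    """
    d = json.loads(Path(path).read_text())
    units = d.pop("calf_units", "m")
    d.pop("standard_errors", None)
    d.pop("method", None)
    d.pop("converged", None)
    d.pop("n_fit", None)
    d["criterion"] = SarcopeniaCriterion.parse(d["criterion"])
    model = LogisticSarcopeniaModel(**d)
    if units == "cm":
        model.b_calf *= 100.0
    elif units != "m":
        raise ValueError(f"calf_units must be 'cm' or 'm', got {units!r}")
    return model
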