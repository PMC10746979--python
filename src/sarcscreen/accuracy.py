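"""Diagnostic test accuracy: 2x2 tables, metric panels, confidence intervals.

Cross-tabulates an index test against a reference standard and computes the
standard panel — sensitivity, specificity, accuracy, predictive values,
likelihood ratios, false positives/negatives per 100 tested, and AUC — each
with a 95% CI.  Also reconstructs integer 2x2 tables from published summary
statistics (n, case count, sensitivity, specificity rounded to one decimal),
which turns printed accuracy tables into exact regression tests.

CI methods (selectable via :class:`CIConfig`): Wilson score for proportions,
the Simel log method for likelihood ratios, Hanley–McNeil (or DeLong) for AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "DiagnosticReport",
    "CIConfig",
    "ReconstructionError",
    "round_half_up",
    "confusion_from_predictions",
    "confusion_from_summary",
    "metrics",
    "confidence_intervals",
    "auc_mann_whitney",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero toward +inf (the usual table convention)."""
    scale = 10.0**ndigits
    # tiny epsilon absorbs float representation error in ratios like 77.15
    return math.floor(x * scale + 0.5 + 1e-9) / scale


@dataclass(frozen=True)
class ConfusionTable:
    """Integer 2x2 cross-tabulation; the reference standard is the truth axis."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def cases(self) -> int:
        return self.tp + self.fn

    @property
    def noncases(self) -> int:
        return self.fp + self.tn


@dataclass
class DiagnosticReport:
    """Full metric panel.  Proportions are percentages; likelihood ratios are
    plain ratios; ``nnm_fp``/``nnm_fn`` are counts per 100 tested.  A metric
    whose denominator is zero is ``None`` and listed in ``undefined``;
    an infinite likelihood ratio is ``math.inf``."""

    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    ppv: float | None = None
    npv: float | None = None
    plr: float | None = None
    nlr: float | None = None
    nnm_fp: float | None = None
    nnm_fn: float | None = None
    auc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)

    _PERCENT = ("sensitivity", "specificity", "accuracy", "ppv", "npv", "auc")
    _RATIO = ("plr", "nlr", "nnm_fp", "nnm_fn")

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Point estimates rounded half-up, as printed in reports."""
        out: dict[str, float | None] = {}
        for name in self._PERCENT + self._RATIO:
            v = getattr(self, name)
            out[name] = None if v is None else (
                math.inf if math.isinf(v) else round_half_up(v, ndigits)
            )
        return out

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._PERCENT + self._RATIO}
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        d["undefined"] = list(self.undefined)
        return d


@dataclass
class CIConfig:
    """Confidence-interval method selection (all 95% two-sided)."""

    proportion: str = "wilson"  # wilson | wald | agresti_coull | beta (Clopper-Pearson)
    likelihood_ratio: str = "log"  # Simel log method
    auc: str = "hanley-mcneil"  # hanley-mcneil | delong
    level: float = 0.95


class ReconstructionError(ValueError):
    """No integer cell count reproduces the printed summary statistic."""


def confusion_from_predictions(index_labels, reference_labels) -> ConfusionTable:
    """Tally a 2x2 table from aligned binary label vectors (1 = positive)."""
    idx = np.asarray(index_labels)
    ref = np.asarray(reference_labels)
    if idx.shape != ref.shape or idx.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length, got {idx.shape} vs {ref.shape}"
        )
    for name, v in (("index", idx), ("reference", ref)):
        if not np.isin(v, (0, 1, True, False)).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    idx = idx.astype(bool)
    ref = ref.astype(bool)
    return ConfusionTable(
        tp=int((idx & ref).sum()),
        fp=int((idx & ~ref).sum()),
        fn=int((~idx & ref).sum()),
        tn=int((~idx & ~ref).sum()),
    )


def _match_count(total: int, target_pct: float, what: str) -> int:
    """Smallest-error integer k in [0, total] with 100*k/total printing as target_pct."""
    if total == 0:
        raise ReconstructionError(f"cannot reconstruct {what}: zero denominator")
    ks = np.arange(total + 1)
    pct = 100.0 * ks / total
    rounds_to = np.array([round_half_up(p, 1) for p in pct])
    candidates = ks[np.isclose(rounds_to, target_pct, atol=1e-9)]
    if candidates.size == 0:
        diffs = np.abs(pct - target_pct)
        nearest = ks[np.argsort(diffs)[:3]]
        raise ReconstructionError(
            f"no integer {what} count in [0, {total}] rounds to {target_pct}%; "
            f"nearest candidates: "
            + ", ".join(f"{k} ({100*k/total:.2f}%)" for k in nearest)
        )
    err = np.abs(100.0 * candidates / total - target_pct)
    best = candidates[np.isclose(err, err.min())]
    if best.size > 1:
        logger.info(
            "reconstruction tie for %s: candidates %s, taking the largest",
            what, best.tolist(),
        )
    return int(best.max())


def confusion_from_summary(
    n: int,
    cases: int,
    sensitivity_pct: float | None,
    specificity_pct: float | None,
) -> ConfusionTable:
    """Recover the integer 2x2 table behind printed (n, cases, sens%, spec%).

    Sensitivity and specificity are assumed printed half-up to one decimal.
    If ``cases`` (respectively non-cases) is zero the corresponding percentage
    must be ``None`` and the column is all zeros.
    """
    if not 0 <= cases <= n:
        raise ValueError(f"cases={cases} must lie in [0, n={n}]")
    noncases = n - cases
    if cases == 0:
        if sensitivity_pct is not None:
            raise ReconstructionError("sensitivity given but there are no cases")
        tp = 0
    else:
        if sensitivity_pct is None:
            raise ReconstructionError("sensitivity required when cases > 0")
        tp = _match_count(cases, float(sensitivity_pct), "true-positive")
    if noncases == 0:
        if specificity_pct is not None:
            raise ReconstructionError("specificity given but there are no non-cases")
        tn = 0
    else:
        if specificity_pct is None:
            raise ReconstructionError("specificity required when non-cases > 0")
        tn = _match_count(noncases, float(specificity_pct), "true-negative")
    return ConfusionTable(tp=tp, fp=noncases - tn, fn=cases - tp, tn=tn)


def metrics(table: ConfusionTable) -> DiagnosticReport:
    """Point estimates of the full panel from a 2x2 table.

    Percentages are exact (round via :meth:`DiagnosticReport.rounded`).
    A likelihood ratio with zero denominator is reported as ``inf``; a
    proportion with zero denominator is ``None`` and flagged undefined.
    """
    rep = DiagnosticReport()
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    n = table.n

    def pct(num, den, name):
        if den == 0:
            rep.undefined.append(name)
            return None
        return 100.0 * num / den

    rep.sensitivity = pct(tp, tp + fn, "sensitivity")
    rep.specificity = pct(tn, tn + fp, "specificity")
    rep.accuracy = 100.0 * (tp + tn) / n
    rep.ppv = pct(tp, tp + fp, "ppv")
    rep.npv = pct(tn, tn + fn, "npv")
    if rep.sensitivity is not None and rep.specificity is not None:
        sens = rep.sensitivity / 100.0
        spec = rep.specificity / 100.0
        rep.plr = math.inf if spec == 1.0 else sens / (1.0 - spec)
        rep.nlr = math.inf if spec == 0.0 else (1.0 - sens) / spec
        if math.isinf(rep.plr):
            rep.undefined.append("plr")  # reported as open/infinite
    else:
        rep.undefined += ["plr", "nlr"]
    rep.nnm_fp = 100.0 * fp / n
    rep.nnm_fn = 100.0 * fn / n
    return rep


def _proportion_ci(count: int, nobs: int, method: str, level: float):
    lo, hi = proportion_confint(count, nobs, alpha=1 - level, method=method)
    return 100.0 * lo, 100.0 * hi


def _lr_ci(table: ConfusionTable, which: str, level: float):
    """Simel log-method CI for likelihood ratios; zero cells give open bounds."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    z = stats.norm.ppf(0.5 + level / 2)
    cases, noncases = table.cases, table.noncases
    if which == "plr":
        if fp == 0:
            return (np.nan, math.inf)  # open interval: no false positives observed
        if tp == 0:
            return (0.0, np.nan)
        lr = (tp / cases) / (fp / noncases)
        se = math.sqrt(1 / tp - 1 / cases + 1 / fp - 1 / noncases)
    else:
        if fn == 0:
            return (0.0, np.nan)
        if tn == 0:
            return (np.nan, math.inf)
        lr = (fn / cases) / (tn / noncases)
        se = math.sqrt(1 / fn - 1 / cases + 1 / tn - 1 / noncases)
    return (lr * math.exp(-z * se), lr * math.exp(z * se))


def confidence_intervals(
    table: ConfusionTable, config: CIConfig | None = None
) -> dict[str, tuple[float, float]]:
    """95% CIs for every defined metric of *table* (see :class:`CIConfig`)."""
    cfg = config or CIConfig()
    ci: dict[str, tuple[float, float]] = {}
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    pairs = {
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "accuracy": (tp + tn, table.n),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
        "nnm_fp": (fp, table.n),
        "nnm_fn": (fn, table.n),
    }
    for name, (count, nobs) in pairs.items():
        if nobs == 0:
            continue
        if count == 0 or count == nobs:
            logger.debug("zero/full cell for %s CI; %s handles the boundary", name, cfg.proportion)
        ci[name] = _proportion_ci(count, nobs, cfg.proportion, cfg.level)
    if table.cases > 0 and table.noncases > 0:
        ci["plr"] = _lr_ci(table, "plr", cfg.level)
        ci["nlr"] = _lr_ci(table, "nlr", cfg.level)
    return ci


def auc_mann_whitney(
    probabilities,
    reference_labels,
    ci_method: str = "hanley-mcneil",
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Concordance (AUC) by the rank statistic, with a 95% CI.

    AUC is the probability that a randomly chosen case receives a higher
    predicted probability than a randomly chosen non-case; ties contribute
    one half (midranks).  CI by Hanley–McNeil by default, DeLong optionally.
    Returned on the probability scale (0–1).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(reference_labels).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(p)  # midranks for ties
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    z = stats.norm.ppf(0.5 + level / 2)
    if ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
            n1 * n0
        )
        se = math.sqrt(max(var, 0.0))
    elif ci_method == "delong":
        # placement-value components (DeLong's structural variance)
        cases, noncases = p[y], p[~y]
        v10 = np.array([
            ((x > noncases).sum() + 0.5 * (x == noncases).sum()) / n0 for x in cases
        ])
        v01 = np.array([
            ((cases > x).sum() + 0.5 * (cases == x).sum()) / n1 for x in noncases
        ])
        var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
        se = math.sqrt(max(var, 0.0))
    else:
        raise ValueError(f"unknown AUC CI method {ci_method!r}")
    return float(auc), (max(0.0, auc - z * se), min(1.0, auc + z * se))
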