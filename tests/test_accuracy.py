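import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sarcscreen.accuracy import (
    CIConfig,
    ConfusionTable,
    ReconstructionError,
    auc_mann_whitney,
    confidence_intervals,
    confusion_from_predictions,
    confusion_from_summary,
    metrics,
    round_half_up,
)


# -- cross-tabulation --------------------------------------------------------

def test_identical_vectors_have_no_errors():
    t = confusion_from_predictions([1, 0, 1, 0], [1, 0, 1, 0])
    assert (t.fp, t.fn) == (0, 0)


def test_complementary_vectors_have_no_hits():
    t = confusion_from_predictions([1, 0, 1], [0, 1, 0])
    assert (t.tp, t.tn) == (0, 0)


def test_counts_match_manual_tally():
    idx = [1, 1, 0, 0, 1, 0, 1, 0, 0, 1]
    ref = [1, 0, 0, 1, 1, 0, 0, 0, 1, 1]
    t = confusion_from_predictions(idx, ref)
    # brute-force tally
    joint = list(zip(idx, ref))
    assert t.tp == joint.count((1, 1)) == 3
    assert t.fp == joint.count((1, 0)) == 2
    assert t.fn == joint.count((0, 1)) == 2
    assert t.tn == joint.count((0, 0)) == 3


def test_length_mismatch_and_nonbinary_rejected():
    with pytest.raises(ValueError):
        confusion_from_predictions([1, 0], [1])
    with pytest.raises(ValueError):
        confusion_from_predictions([1, 2], [1, 0])


# -- reconstruction from printed summaries -----------------------------------

def test_reconstruction_of_published_2x2_tables():
    t = confusion_from_summary(406, 20, 70.0, 77.2)
    assert (t.tp, t.fp, t.fn, t.tn) == (14, 88, 6, 298)
    t = confusion_from_summary(280, 11, 72.7, 94.4)
    assert (t.tp, t.fp, t.fn, t.tn) == (8, 15, 3, 254)


def test_reconstruction_degenerate_no_cases():
    t = confusion_from_summary(10, 0, None, 100.0)
    assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 10)
    with pytest.raises(ReconstructionError):
        confusion_from_summary(10, 0, 50.0, 100.0)


def test_reconstruction_failure_lists_candidates():
    # with 7 cases the sensitivity grid is multiples of 1/7; 50.0% is unreachable
    with pytest.raises(ReconstructionError, match="nearest candidates"):
        confusion_from_summary(100, 7, 50.0, 90.0)


def test_reconstruction_roundtrip_is_self_consistent():
    for cases, n in [(20, 406), (11, 280), (46, 406)]:
        noncases = n - cases
        spec = round_half_up(100 * round(0.8 * noncases) / noncases, 1)
        for tp in range(cases + 1):
            sens = round_half_up(100 * tp / cases, 1)
            t = confusion_from_summary(n, cases, sens, spec)
            assert round_half_up(100 * t.tp / cases, 1) == sens
            assert round_half_up(100 * t.tn / noncases, 1) == spec


# -- metric panel ------------------------------------------------------------

def test_metric_panel_matches_published_cells_women():
    r = metrics(ConfusionTable(14, 88, 6, 298)).rounded()
    assert r["ppv"] == 13.7
    assert r["npv"] == 98.0
    assert r["accuracy"] == 76.8
    assert r["plr"] == 3.1
    assert r["nnm_fp"] == 21.7


def test_metric_panel_matches_published_cells_men():
    r = metrics(ConfusionTable(8, 15, 3, 254)).rounded()
    assert r["ppv"] == 34.8
    assert r["accuracy"] == 93.6
    assert r["nnm_fn"] == 1.1


def test_perfect_test_degenerate_metrics():
    rep = metrics(ConfusionTable(5, 0, 0, 7))
    assert rep.sensitivity == rep.specificity == rep.ppv == rep.npv == 100.0
    assert rep.nlr == 0.0
    assert math.isinf(rep.plr) and "plr" in rep.undefined


def test_zero_denominator_flagged_not_nan():
    rep = metrics(ConfusionTable(0, 3, 0, 7))  # no cases
    assert rep.sensitivity is None and "sensitivity" in rep.undefined
    assert rep.npv is not None


tables = st.tuples(*(st.integers(0, 60),) * 4).filter(
    lambda t: t[0] + t[3] > 0 and t[0] + t[1] > 0 and t[2] + t[3] > 0
    and t[0] + t[2] > 0 and t[1] + t[3] > 0
)


@given(tables)
def test_ppv_equals_bayes_from_tables_own_prevalence(cells):
    tp, fp, fn, tn = cells
    rep = metrics(ConfusionTable(tp, fp, fn, tn))
    prev = (tp + fn) / (tp + fp + fn + tn)
    sens = rep.sensitivity / 100
    spec = rep.specificity / 100
    denominator = sens * prev + (1 - spec) * (1 - prev)
    assert rep.ppv / 100 == pytest.approx(sens * prev / denominator, abs=1e-12)


@given(tables)
def test_informative_test_has_plr_above_one_above_nlr(cells):
    tp, fp, fn, tn = cells
    rep = metrics(ConfusionTable(tp, fp, fn, tn))
    j = rep.sensitivity / 100 + rep.specificity / 100 - 1
    if j > 0 and not math.isinf(rep.plr):
        assert rep.plr > 1 > rep.nlr


# -- confidence intervals ----------------------------------------------------

def test_wilson_interval_matches_closed_form():
    # tp = fn = 50: phat = 0.5, n = 100; Wilson center/width in closed form
    ci = confidence_intervals(ConfusionTable(50, 10, 50, 10))["sensitivity"]
    z = 1.959963984540054
    n = 100
    center = (0.5 + z**2 / (2 * n)) / (1 + z**2 / n)
    half = (z / (1 + z**2 / n)) * math.sqrt(0.25 / n + z**2 / (4 * n**2))
    assert ci[0] == pytest.approx(100 * (center - half), abs=1e-9)
    assert ci[1] == pytest.approx(100 * (center + half), abs=1e-9)
    assert ci[0] + ci[1] == pytest.approx(100 * 2 * center, abs=1e-9)


def test_wilson_approaches_wald_at_large_n():
    n = 10**5
    t = ConfusionTable(tp=int(0.3 * n), fn=n - int(0.3 * n), fp=10, tn=10)
    wilson = confidence_intervals(t, CIConfig(proportion="wilson"))["sensitivity"]
    p = 0.3
    half = 1.959963984540054 * math.sqrt(p * (1 - p) / n)
    wald = (100 * (p - half), 100 * (p + half))
    assert wilson[0] == pytest.approx(wald[0], abs=0.1)
    assert wilson[1] == pytest.approx(wald[1], abs=0.1)


def test_plr_open_interval_when_no_false_positives():
    ci = confidence_intervals(ConfusionTable(5, 0, 2, 20))
    assert math.isinf(ci["plr"][1])


def test_point_estimates_lie_inside_their_intervals():
    t = ConfusionTable(14, 88, 6, 298)
    rep = metrics(t)
    for name, (lo, hi) in confidence_intervals(t).items():
        v = getattr(rep, name)
        assert lo - 1e-9 <= v <= hi + 1e-9


# -- AUC ---------------------------------------------------------------------

def _auc_pair_counting(probs, labels):
    cases = [p for p, y in zip(probs, labels) if y]
    noncases = [p for p, y in zip(probs, labels) if not y]
    total = 0.0
    for c in cases:
        for h in noncases:
            total += 1.0 if c > h else (0.5 if c == h else 0.0)
    return total / (len(cases) * len(noncases))


def test_auc_perfect_separation_is_one():
    auc, _ = auc_mann_whitney([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert auc == 1.0


def test_auc_equals_pair_counting_on_toy_sets():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = rng.integers(4, 9)
        labels = np.zeros(n, dtype=int)
        labels[: rng.integers(1, n)] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            continue
        probs = rng.choice([0.1, 0.3, 0.3, 0.5, 0.7, 0.9], size=n)
        auc, _ = auc_mann_whitney(probs, labels)
        assert auc == pytest.approx(_auc_pair_counting(probs, labels), abs=1e-12)


def test_auc_equals_trapezoidal_roc_area():
    rng = np.random.default_rng(11)
    probs = rng.random(60)
    labels = (rng.random(60) < 0.4).astype(int)
    auc, _ = auc_mann_whitney(probs, labels)
    # empirical ROC by threshold sweep over all distinct values
    thresholds = np.concatenate(([np.inf], np.sort(np.unique(probs))[::-1], [-np.inf]))
    pts = []
    for thr in thresholds:
        pos = probs >= thr
        tpr = (pos & (labels == 1)).sum() / (labels == 1).sum()
        fpr = (pos & (labels == 0)).sum() / (labels == 0).sum()
        pts.append((fpr, tpr))
    pts = np.array(pts)
    area = np.trapezoid(pts[:, 1], pts[:, 0])
    assert auc == pytest.approx(area, abs=1e-12)


def test_auc_near_half_for_uninformative_probabilities():
    rng = np.random.default_rng(3)
    probs = rng.random(2000)
    labels = (rng.random(2000) < 0.5).astype(int)
    auc, _ = auc_mann_whitney(probs, labels)
    assert auc == pytest.approx(0.5, abs=0.03)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc_mann_whitney([0.1, 0.2], [1, 1])


def test_delong_and_hanley_intervals_agree_roughly():
    rng = np.random.default_rng(5)
    probs = np.concatenate([rng.normal(0.6, 0.15, 40), rng.normal(0.4, 0.15, 160)])
    labels = np.array([1] * 40 + [0] * 160)
    a1, ci1 = auc_mann_whitney(probs, labels, ci_method="hanley-mcneil")
    a2, ci2 = auc_mann_whitney(probs, labels, ci_method="delong")
    assert a1 == a2
    assert ci1[0] == pytest.approx(ci2[0], abs=0.05)
    assert ci1[1] == pytest.approx(ci2[1], abs=0.05)
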