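import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import sarcscreen as s
from sarcscreen.classifier import (
    NoDiscriminationError,
    SeparationWarning,
    UnfittableError,
    _operating_point,
)
from tests.conftest import CLASSIFIER_TRUTH


def make_model(b0=0.0, b_power=0.0, b_calf=0.0, cutoff=None):
    return s.LogisticSarcopeniaModel(
        sex="female", criterion=s.SarcopeniaCriterion.HG_ASM,
        b0=b0, b_power=b_power, b_calf=b_calf, cutoff_probability=cutoff,
    )


def frame(probs, labels, model):
    """Cohort frame whose predicted probabilities equal *probs* under *model*.

    Uses b_power = 1, b_calf = 0 and power = logit(p).
    """
    from scipy.special import logit

    return pd.DataFrame({
        "sex": "female",
        "power_wkg": logit(np.asarray(probs)),
        "calf_circumference_m": 0.36,
        "sarc_hg_asm": labels,
    })


# -- prediction and classification -------------------------------------------

def test_null_model_predicts_half_everywhere():
    m = make_model()
    assert s.predict_probability(m, 5.0, 0.36) == 0.5


def test_probability_limits_and_overflow_guard():
    m = make_model(b_power=1.0)
    assert s.predict_probability(m, 1e6, 0.36) == pytest.approx(1.0)
    assert s.predict_probability(m, -1e6, 0.36) == pytest.approx(0.0)
    assert np.isfinite(s.predict_probability(m, 1e300, 0.0))


def test_boundary_probability_classifies_positive():
    m = make_model(cutoff=0.5)  # p = 0.5 exactly at any input
    assert s.classify(m, 5.0, 0.36) == 1


def test_extreme_probabilities_classify_consistently():
    m = make_model(b_power=1.0, cutoff=0.0503135)
    assert s.classify(m, -100.0, 0.36) == 0  # p ~ 0 -> healthy
    assert s.classify(m, 100.0, 0.36) == 1   # p ~ 1 -> sarcopenic


def test_low_power_low_calf_woman_flagged_with_plausible_coefficients():
    # risk decreases with power and calf; a slow rise with small calf must flag
    m = make_model(b0=15.0, b_power=-1.5, b_calf=-30.0, cutoff=0.0503135)
    p = s.predict_probability(m, s.vertical_power(1.2, 0.39), 0.332)
    assert p >= m.cutoff_probability
    assert s.classify(m, s.vertical_power(1.2, 0.39), 0.332) == 1


def test_classification_monotone_in_protective_power():
    m = make_model(b0=15.0, b_power=-1.5, b_calf=-30.0, cutoff=0.1)
    labels = [s.classify(m, p, 0.34) for p in np.linspace(2, 9, 50)]
    # once healthy, more power never flips back to sarcopenic
    assert sorted(labels, reverse=True) == labels


# -- fitting -----------------------------------------------------------------

def test_fit_recovers_generating_coefficients(truth_cohort, truth_model):
    se = truth_model.standard_errors
    for name, true_val in zip(("b0", "b_power", "b_calf"), CLASSIFIER_TRUTH):
        est = getattr(truth_model, name)
        assert abs(est - true_val) < 3 * se[name], name


def test_fit_null_labels_gives_near_zero_slopes(rng):
    n = 2000
    df = pd.DataFrame({
        "sex": "female",
        "power_wkg": rng.normal(5, 1.1, n),
        "calf_circumference_m": rng.normal(0.36, 0.03, n),
        "sarc_hg_asm": rng.random(n) < 0.3,
    })
    m = s.fit_model(df, "female", "hg_asm")
    assert abs(m.b_power) < 3 * m.standard_errors["b_power"]
    assert abs(m.b_calf) < 3 * m.standard_errors["b_calf"]


def test_single_class_labels_unfittable():
    df = pd.DataFrame({
        "sex": "female",
        "power_wkg": np.linspace(3, 7, 30),
        "calf_circumference_m": 0.36,
        "sarc_hg_asm": 1,
    })
    with pytest.raises(UnfittableError):
        s.fit_model(df, "female", "hg_asm")


def test_tiny_cohort_rejected():
    df = pd.DataFrame({
        "sex": "female", "power_wkg": [4, 5, 6], "calf_circumference_m": 0.36,
        "sarc_hg_asm": [1, 0, 1],
    })
    with pytest.raises(UnfittableError, match=">= 10"):
        s.fit_model(df, "female", "hg_asm")


def test_perfect_separation_falls_back_to_firth():
    power = np.concatenate([np.linspace(2, 4, 15), np.linspace(5, 8, 15)])
    df = pd.DataFrame({
        "sex": "female",
        "power_wkg": power,
        "calf_circumference_m": np.linspace(0.3, 0.42, 30),
        "sarc_hg_asm": (power < 4.5).astype(int),
    })
    with pytest.warns(SeparationWarning):
        m = s.fit_model(df, "female", "hg_asm")
    assert m.method == "firth"
    assert np.isfinite([m.b0, m.b_power, m.b_calf]).all()
    assert m.b_power < 0  # low power still predicts the label


# -- cutoff selection --------------------------------------------------------

def test_separated_probabilities_give_midpoint_cutoff():
    m = make_model(b_power=1.0)
    df = frame([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], m)
    cut = s.select_cutoff(m, df)
    assert cut == pytest.approx(0.5)
    probs = np.array([0.1, 0.2, 0.8, 0.9])
    sens, spec = _operating_point(probs, np.array([0, 0, 1, 1]), cut)
    assert sens == spec == 1.0


def _brute_force_youden(probs, labels):
    """Exhaustive scan over every threshold between -inf and +inf."""
    candidates = np.concatenate(([0.0, 1.0], np.sort(np.unique(probs)),
                                 (np.sort(np.unique(probs))[:-1] + np.sort(np.unique(probs))[1:]) / 2))
    best = None
    for c in candidates:
        sens, spec = _operating_point(probs, labels, c)
        j = sens + spec - 1
        if best is None or (j, sens) > best[:2]:
            best = (j, sens, c)
    return best


def test_youden_cutoff_matches_exhaustive_enumeration():
    m = make_model(b_power=1.0)
    probs = np.array([0.05, 0.2, 0.3, 0.45, 0.6, 0.8])
    labels = np.array([0, 0, 1, 0, 1, 1])
    df = frame(probs, labels, m)
    cut = s.select_cutoff(m, df)
    j_best, sens_best, _ = _brute_force_youden(probs, labels)
    sens, spec = _operating_point(probs, labels, cut)
    assert sens + spec - 1 == pytest.approx(j_best, abs=1e-12)
    assert sens == pytest.approx(sens_best, abs=1e-12)


def test_uninformative_probabilities_warn_of_low_j(rng):
    m = make_model(b_power=1.0)
    probs = rng.random(3000)
    labels = (rng.random(3000) < 0.3).astype(int)
    df = frame(probs, labels, m)
    with pytest.warns(UserWarning, match="barely discriminates"):
        cut = s.select_cutoff(m, df)
    sens, spec = _operating_point(
        df.power_wkg.map(lambda x: 1 / (1 + np.exp(-x))).to_numpy(), labels, cut
    )
    assert sens + spec - 1 < 0.06


def test_constant_probabilities_cannot_discriminate():
    m = make_model()  # all predictions 0.5
    df = frame([0.3] * 20, [0, 1] * 10, m)
    df["power_wkg"] = 0.0
    with pytest.raises(NoDiscriminationError):
        s.select_cutoff(m, df)


def test_selected_operating_point_consistent_with_confusion_metrics(truth_cohort, truth_model):
    model = truth_model
    cut = s.select_cutoff(model, truth_cohort, label_col="sarc_model")
    sub = truth_cohort
    probs = s.predict_probability(
        model, sub.power_wkg.to_numpy(), sub.calf_circumference_m.to_numpy()
    )
    idx = (probs >= cut).astype(int)
    table = s.confusion_from_predictions(idx, sub.sarc_model.to_numpy())
    rep = s.metrics(table)
    sens, spec = _operating_point(probs, sub.sarc_model.to_numpy(), cut)
    assert rep.sensitivity == pytest.approx(100 * sens, abs=1e-9)
    assert rep.specificity == pytest.approx(100 * spec, abs=1e-9)


# -- calibration -------------------------------------------------------------

def test_hosmer_lemeshow_detects_miscalibration(rng):
    n = 5000
    p_true = rng.beta(2, 6, n)
    y = (rng.random(n) < p_true).astype(int)
    stat_ok, df_ok, p_ok = s.hosmer_lemeshow(p_true, y)
    assert df_ok == 8
    assert p_ok > 0.01
    # squared probabilities are badly miscalibrated
    _, _, p_bad = s.hosmer_lemeshow(p_true**2, y)
    assert p_bad < 1e-4


def test_hosmer_lemeshow_too_few_groups_rejected():
    with pytest.raises(ValueError):
        s.hosmer_lemeshow([0.2, 0.8], [0, 1], groups=2)


# -- bootstrap internal validation -------------------------------------------

def test_bootstrap_reproducible_bit_for_bit(truth_cohort, truth_model):
    kw = dict(B=25, seed=99, label_col="sarc_model")
    d1 = s.bootstrap_optimism(truth_model, truth_cohort, **kw)
    d2 = s.bootstrap_optimism(truth_model, truth_cohort, **kw)
    assert d1.optimism == d2.optimism
    assert d1.corrected_c == d2.corrected_c


def test_bootstrap_invalid_b_rejected(truth_cohort, truth_model):
    with pytest.raises(ValueError):
        s.bootstrap_optimism(truth_model, truth_cohort, B=0)


def test_small_overfit_cohort_shows_positive_optimism(rng):
    n = 40
    df = pd.DataFrame({
        "sex": "female",
        "power_wkg": rng.normal(5, 1.1, n),
        "calf_circumference_m": rng.normal(0.36, 0.03, n),
    })
    # 5 events, unrelated to covariates: apparent c is pure overfit
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, 5, replace=False)] = 1
    df["sarc_hg_asm"] = labels
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = s.fit_model(df, "female", "hg_asm")
        diag = s.bootstrap_optimism(m, df, B=100, seed=4)
    # an order of magnitude above the well-powered regime (< 0.004)
    assert diag.optimism > 0.01


# -- model config round trip --------------------------------------------------

def test_model_json_roundtrip_and_cm_coefficient_rescaling(tmp_path):
    m = make_model(b0=12.0, b_power=-1.4, b_calf=-28.0, cutoff=0.0503135)
    path = tmp_path / "model.json"
    s.save_model_json(m, path)
    loaded = s.load_model_json(path)
    assert (loaded.b0, loaded.b_power, loaded.b_calf) == (12.0, -1.4, -28.0)
    assert loaded.cutoff_probability == 0.0503135
    # a config quoting the calf coefficient per centimeter
    import json

    d = json.loads(path.read_text())
    d["b_calf"] = -0.28
    d["calf_units"] = "cm"
    path.write_text(json.dumps(d))
    loaded_cm = s.load_model_json(path)
    assert loaded_cm.b_calf == pytest.approx(-28.0)
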