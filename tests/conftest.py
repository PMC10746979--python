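import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import sarcscreen as s

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: The eight published sex x criterion accuracy panels, as
#: (sex, criterion, n, cases, sensitivity %, specificity %).
TABLE_PANELS = [
    ("female", "hg_asm", 406, 20, 70.0, 77.2),
    ("female", "hg_smi", 406, 7, 71.4, 89.5),
    ("female", "5sts_asm", 406, 46, 71.7, 78.1),
    ("female", "5sts_smi", 406, 18, 77.8, 86.1),
    ("male", "hg_asm", 280, 11, 72.7, 94.4),
    ("male", "hg_smi", 280, 7, 71.4, 94.9),
    ("male", "5sts_asm", 280, 30, 80.0, 87.6),
    ("male", "5sts_smi", 280, 24, 83.3, 86.7),
]

#: Logistic ground truth used in recovery experiments: intercept, per-W/kg
#: power slope, per-meter calf slope (lower power/calf -> higher risk).
CLASSIFIER_TRUTH = (15.0, -1.5, -30.0)


@pytest.fixture(scope="session")
def truth_cohort() -> pd.DataFrame:
    """2000 women drawn with known logistic truth (labels in sarc_model)."""
    spec = s.default_spec()
    spec.n_female, spec.n_male = 2000, 0
    spec.classifier_truth = CLASSIFIER_TRUTH
    return s.generate(spec, seed=20230101)


@pytest.fixture(scope="session")
def truth_model(truth_cohort) -> s.LogisticSarcopeniaModel:
    return s.fit_model(truth_cohort, "female", "hg_asm", label_col="sarc_model")


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """Study-sized cohort (406 women / 280 men) under default conditions."""
    return s.generate(s.default_spec(), seed=20230202)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
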