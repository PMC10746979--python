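"""Construct validity: do screen positives carry more adverse outcomes?

A valid sarcopenia screen should flag people with more health-related risk
factors and frailty.  This example classifies a synthetic cohort with the
fitted index test, then computes unadjusted and age/sex/BMI-adjusted odds
ratios of each risk factor among screen positives vs negatives (one-tailed
tests in the direction OR > 1).
"""

import warnings

import numpy as np
import pandas as pd

import sarcscreen as s
from sarcscreen.construct import ExposureTable

warnings.filterwarnings("ignore")

cohort = s.generate(s.default_spec(), seed=20230202)
criterion = "5sts_asm"

# per-sex index-test labels, pooled for the whole-cohort odds ratios
app = pd.Series(0, index=cohort.index)
for sex in ("female", "male"):
    model = s.fit_model(cohort, sex, criterion)
    model.cutoff_probability = s.select_cutoff(model, cohort)
    mask = cohort.sex == sex
    app[mask] = s.classify(
        model,
        cohort.loc[mask, "power_wkg"].to_numpy(),
        cohort.loc[mask, "calf_circumference_m"].to_numpy(),
    )
cohort["app_sarcopenia"] = app

print(f"{'risk factor':26s} {'OR':>6s} {'adj OR':>7s}  (one-tailed p, adjusted)")
for factor in ("education_low", "comorbidity_2plus", "polypharmacy_5plus",
               "self_perceived_health_low", "falls_2plus", "frail"):
    exposed = cohort[factor].astype(bool)
    case = cohort["app_sarcopenia"].astype(bool)
    unadj = s.unadjusted_or(ExposureTable(
        int((exposed & case).sum()), int((exposed & ~case).sum()),
        int((~exposed & case).sum()), int((~exposed & ~case).sum()),
    ))
    adj = s.adjusted_or(cohort, factor, label_col="app_sarcopenia")
    print(f"{factor:26s} {unadj.odds_ratio:6.2f} {adj.odds_ratio:7.2f}  (p={adj.p_one_tailed:.3f})")

print("\nOdds ratios above 1 mean screen positives carry the adverse outcome")
print("more often; in this synthetic cohort the association is induced through")
print("a low-power/low-calf latent, mimicking the construct the screen targets.")
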