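# sarcscreen

Sit-to-stand kinematic power estimation and sarcopenia screening.

Sarcopenia — the age-related loss of muscle strength *and* muscle mass — is
underdiagnosed in community settings because its reference-standard
measurements (handgrip dynamometry, bioimpedance body composition) need
equipment and time most clinics lack. A practical alternative is to film a
single chair rise with a high-speed smartphone camera, estimate body-mass
relative **vertical power** from the rising time and femur length, and combine
it with a tape-measured **calf circumference** in a sex-stratified logistic
model. `sarcscreen` implements that index test end to end, together with the
EWGSOP2 reference standards it is validated against and the full
diagnostic-accuracy machinery used to evaluate it. It is written for
biostatisticians and clinical researchers who develop or appraise screening
tools of this kind.

## The model

Vertical power (W/kg) during the rising phase (duration *t* seconds, femur
length *d* meters, frames selected on a 240-fps recording):

```
P = 2.773 − 6.228·t + 18.224·d
```

The index test is, per sex and per reference standard,

```
p = 1 / (1 + e^(−z)),   z = β₀ + β₁·P + β₂·calf
```

with a positive screen when `p ≥ cutoff`; the cutoff is chosen on the ROC of
predicted probabilities (Youden's *J* by default). The reference standard is
EWGSOP2 sarcopenia: low strength (handgrip < 27/16 kg men/women, or five-times
sit-to-stand > 15 s) **and** low quantity (ASM < 20/15 kg, or SMI < 7/5.5
kg/m²), in any of the four strength × quantity combinations.

The package provides:

- `kinematics` — rising time, vertical velocity, vertical power from a frame pair;
- `ewgsop2` — the four reference standards, plus the Fried frailty phenotype (≥ 3 of 5 criteria);
- `classifier` — sex-stratified logistic fits (Firth fallback under separation),
  ROC cutoff selection, Hosmer–Lemeshow calibration, Harrell bootstrap optimism
  correction of the c-statistic;
- `accuracy` — 2×2 tables, the full metric panel (sensitivity, specificity,
  accuracy, PPV/NPV, PLR/NLR, false positives/negatives per 100 tested, AUC)
  with Wilson / Simel / Hanley–McNeil 95% CIs, and exact reconstruction of
  integer 2×2 tables from published summary statistics;
- `construct` — unadjusted and age/sex/BMI-adjusted odds ratios of
  health-related risk factors among screen positives (one-tailed);
- `cohort` — a Gaussian-copula synthetic-cohort generator encoding the study
  conditions (406 women / 280 men, published marginals) with prevalence
  calibration;
- `io` / `cli` — CSV ingest with cm/m unit handling, a validated run
  configuration, the full study pipeline, and a thin `sarcscreen` command-line
  interface (`simulate`, `fit`, `select-cutoff`, `validate-internal`,
  `classify`, `evaluate`, `reconstruct`, `construct-validity`, `run-study`).

## Worked example

Rebuilding a diagnostic-accuracy panel from four published numbers — cohort
size, case count, sensitivity and specificity are enough to recover the
underlying integer 2×2 table exactly, and with it every remaining metric:

```python
from sarcscreen import confusion_from_summary, metrics

table = confusion_from_summary(n=406, cases=20,
                               sensitivity_pct=70.0, specificity_pct=77.2)
print(table)                       # ConfusionTable(tp=14, fp=88, fn=6, tn=298)
print(metrics(table).rounded())
```

prints

```
ConfusionTable(tp=14, fp=88, fn=6, tn=298)
{'sensitivity': 70.0, 'specificity': 77.2, 'accuracy': 76.8, 'ppv': 13.7,
 'npv': 98.0, 'auc': None, 'plr': 3.1, 'nlr': 0.4, 'nnm_fp': 21.7, 'nnm_fn': 1.5}
```

At 4.9% prevalence, a sensitivity of 70% and specificity of 77% yield a PPV of
only 13.7% but an NPV of 98.0% — the screen's value is *ruling out* the
disease; 21.7 of every 100 tested are false positives, 1.5 false negatives.

The `examples/` directory holds one short script per capability (kinematics,
reference standards, panel reconstruction, the simulate→fit→validate pipeline,
construct-validity odds ratios); each prints its numbers with a line on what
they mean. Run e.g.:

```sh
python examples/simulate_fit_validate.py
```

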