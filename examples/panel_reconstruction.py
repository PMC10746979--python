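"""Rebuilding a full diagnostic-accuracy panel from four printed numbers.

Published accuracy tables usually print cohort size, case count, sensitivity
and specificity — enough to recover the underlying integer 2x2 table exactly,
and from it every remaining metric (predictive values, likelihood ratios,
false positives/negatives per 100 tested) with confidence intervals.
"""

from sarcscreen import confusion_from_summary, metrics, confidence_intervals

# women, handgrip + appendicular-mass standard: 406 tested, 20 cases,
# sensitivity 70.0%, specificity 77.2%
table = confusion_from_summary(n=406, cases=20, sensitivity_pct=70.0, specificity_pct=77.2)
print(f"reconstructed table: TP={table.tp} FP={table.fp} FN={table.fn} TN={table.tn}")

report = metrics(table)
ci = confidence_intervals(table)
for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "plr", "nlr", "nnm_fp", "nnm_fn"):
    value = report.rounded()[name]
    lo, hi = ci.get(name, (float("nan"),) * 2)
    print(f"{name:12s} {value:6.1f}   (95% CI {lo:6.1f} – {hi:6.1f})")

print()
print("With 4.9% prevalence a PPV of ~14% and NPV of ~98% are exactly what")
print("Bayes' rule dictates: the test's strength is ruling sarcopenia out.")
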