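# Methods

## The screening model

The index test estimates body-mass-relative vertical power during the rising
phase of a single chair rise from two operator-selected video frames:
`t = (end_frame − start_frame) / fps`, and

    P (W/kg) = 2.773 − 6.228·t + 18.224·d

with `d` the femur length in meters (greater trochanter to lateral condyle, a
proxy for the vertical distance travelled by the pelvis). The regression is a
fixed, externally validated equation; its coefficients are constants here, not
refit. Power is linear, so it can be negative for very slow rises (t beyond
~2 s at typical femur lengths); such values are reported as-is with a warning
rather than clamped, because a floor would hide frame-selection errors. The
choice of frames is manual by design and therefore an input.

Screening combines power with calf circumference (a muscle-quantity proxy) in
a logistic model fit separately per sex and per reference standard:
`logit(p) = β₀ + β₁·P + β₂·calf`, positive screen when `p ≥ cutoff`. The
boundary is included (`≥`) so that the operating point selected on the ROC
reproduces exactly the sensitivity observed in the scan.

## Reference standards

EWGSOP2 confirms sarcopenia when muscle strength and muscle quantity are both
low. Strength: handgrip < 27 kg (men) / < 16 kg (women), or five-times
sit-to-stand time > 15 s. Quantity: ASM < 20 / < 15 kg, or SMI < 7 / < 5.5
kg/m². All comparisons are strict inequalities — a value exactly at its cutoff
is *not low* — because every published cutoff is phrased strictly. The four
strength × quantity combinations are four distinct reference standards;
records missing a needed measurement are excluded from that standard only and
logged. ASM/SMI are inputs (the bioimpedance conversion equation is
population-specific and not re-implemented; a hook accepts a user-supplied
converter). Frailty is the Fried phenotype: at least 3 of 5 criteria.

## Fitting, cutoff, calibration, internal validation

Maximum-likelihood logistic fits use iteratively reweighted least squares via
statsmodels. Complete or quasi-complete separation — likely in small strata
with single-digit event counts — falls back to Jeffreys-prior (Firth)
penalized likelihood, implemented by Newton iteration on the bias-corrected
score; the fallback is flagged on the returned model and in a warning.
Fits require ≥ 10 usable rows and both outcome classes.

The probability cutoff is selected by scanning candidate thresholds — the
midpoints between consecutive distinct predicted probabilities, plus 0 and 1
sentinels (this candidate set realizes every achievable confusion table).
The default criterion is Youden's J = sensitivity + specificity − 1, ties
broken toward higher sensitivity, then toward the lower cutoff for
determinism. "Closest to the (0,1) ROC corner" and fixed-sensitivity rules
are available, since "best cutoff" is convention-dependent.

Calibration uses the Hosmer–Lemeshow deciles-of-risk test (default 10 groups,
df = groups − 2); bins with vanishing expected counts are merged into a
neighbor and the merge logged. Discrimination is the c-statistic computed by
the rank (Mann–Whitney) formulation with midrank ties. Internal validation is
Harrell's bootstrap: for each of B resamples (default 1000), refit, take the
difference between the refit's c on the resample and on the original data;
the mean difference is the optimism, subtracted from the apparent c.
Resamples that lose an outcome class are skipped and counted. The procedure
is bit-reproducible given its seed (default 20220201, arbitrary, always
overridable).

## Diagnostic accuracy

Metrics follow the standard definitions (sensitivity tp/(tp+fn), PLR =
sens/(1−spec), NNM_FP = 100·fp/n, etc.). `nnm_fp`/`nnm_fn` are read as false
positives (negatives) per 100 individuals *tested* — the only reading
consistent with all published values this package reconstructs (e.g.
88/406·100 = 21.7). Reported percentages round half-up to one decimal, the
convention verified by the eight-panel round-trip test.

CI methods are a design choice because published accuracy tables rarely state
them: Wilson score for all proportions (Wald, Agresti–Coull and
Clopper–Pearson selectable), the Simel log method for likelihood ratios
(open-ended at zero cells), Hanley–McNeil for AUC (DeLong selectable). Point
estimates are reproduced exactly in reconstruction tests; printed CIs are not
targeted, since the generating method is unknown.

`confusion_from_summary` recovers the integer 2×2 behind printed
(n, cases, sensitivity, specificity): it searches the integer in [0, cases]
whose percentage prints (half-up, one decimal) as the stated sensitivity
(nearest on ties, larger count preferred, logged), likewise for true
negatives, and errors listing the nearest candidates when no integer matches.
Whether the original table used half-up or half-even rounding is untestable
at one-decimal precision; half-up is assumed and verified self-consistent.

## Construct validity

Unadjusted odds ratios are the cross-product ad/bc with a Woolf log-method CI;
zero cells receive the Haldane–Anscombe 0.5 correction, flagged. Adjusted
odds ratios come from a logistic model controlling age, sex and BMI. The
regression direction is ambiguous in this design; the default models the risk
factor as outcome with screen status as predictor ("screen positives have
higher odds of the factor"), with the reverse direction available by flag.
P-values are one-tailed (H1: OR > 1, the unidirectional rationale that a
sarcopenia screen should only *increase* adverse-outcome odds); CIs remain
two-sided 95%. Constant covariates are dropped with a warning; separation
falls back to the Firth fit.

## Synthetic cohorts

The generator emulates a screening cohort of 686 community-dwelling older
adults (406 women, 280 men, ages 60–88). Variables published as mean (SD) are
normal (power: 5.0 (1.1) women, 5.89 (1.0) men; grip 22.6 (4.3) / 37.5 (6.8)
kg; height 1.55 (0.06) / 1.68 (0.06) m); variables published as median (IQR)
are log-normal matched to the quartiles via ln(q75/q25) = 2·z₀.₇₅·σ (calf
0.36 / 0.37 m medians; femur 0.36 / 0.39 m; 5STS ≈ 12 s; ASM 14.4 / 20.2 kg;
weight, age likewise). Variables are coupled by a Gaussian copula: Spearman
targets are converted to latent Pearson correlations by r = 2·sin(π·ρ/6), the
matrix repaired to the nearest PSD if infeasible (warning). Default rank
correlations (power↔5STS −0.6, calf↔ASM +0.6, grip↔power +0.4, plus weak
height/weight/femur couplings) are plausible placeholders — the study's true
correlations are unpublished — and are fully overridable; recovery tests
therefore validate internal consistency of the pipeline, not the original
data.

SMI and BMI are derived (ASM/height², weight/height²) so the intra-record
consistency invariant holds by construction. The chair-rise frame pair is
back-solved from drawn power and femur length through the inverted power
equation and quantized to the 240-fps grid (max power discrepancy 6.228/480 ≈
0.013 W/kg; rises are floored at 2 frames). Reference labels are induced by
the EWGSOP2 rules on the drawn measurements, which yields prevalences in the
study's 2–11% range under the default marginals. Risk-factor and frailty
booleans are Bernoulli draws at the study's marginal frequencies with odds
multiplied ≈ 2.5-fold for participants in the low-power/low-calf quintile — a
deliberately simple association structure that makes construct-validity
machinery testable; it does not model the real covariance of comorbidity,
and the Fried "weakness" component reuses the grip cutoff. Passing tests on
these cohorts demonstrate correctness of the computations and recoverability
of known truths, not performance on real populations: the generator has no
missingness mechanism, no center effects, and exact marginals.

`calibrate_prevalence` shifts the location of the criterion's strength
marginal (grip down, or 5STS up) and of the ASM marginal (down; SMI-based
criteria are calibrated through ASM since SMI is derived) by a common
multiple of each marginal's scale, found by bisection on a 10⁵-draw
Monte-Carlo cohort with common random numbers, to within ±0.5 percentage
points of target (≤ 60 iterations, error with trace otherwise). Prevalence is
monotone in the shift, so bisection is exact up to Monte-Carlo noise
(SE ≈ 0.07 pp at 5% prevalence).

## Numerical choices and problem sizes

Linear predictors are clamped to ±700 before exponentiation. Bootstrap
optimism experiments in the tests and the acceptance script use B = 200–300
at n = 2000 and n = 686; coefficient-recovery checks use n = 2000 per sex
with truth (β₀, β₁, β₂) = (15, −1.5, −30) (≈ 10% prevalence, AUC ≈ 0.86) and
a 3-standard-error acceptance band; cohort-fidelity checks use n = 10⁴ per
sex (Monte-Carlo SE on the power mean ≈ 0.011 W/kg); prevalence calibration
uses n = 10⁵. The Hosmer–Lemeshow null-size check uses 200 replicates at
n = 5000. These sizes give comfortable margins between statistical tolerance
and Monte-Carlo noise while keeping the default suite fast.

## Known limitations

- The study's fitted coefficients and per-panel cutoffs are not published in
  machine-readable form; shipped models are fit on synthetic cohorts, and
  externally supplied coefficient JSONs (including per-centimeter calf
  coefficients, rescaled on load) are supported instead.
- Published Table-style confidence intervals are not reproduced (method
  unknown); only point estimates are.
- The adjusted-OR direction and the cutoff-selection criterion are
  conventions, selectable but not verifiable against the original analysis.
- The synthetic cohort validates software, not epidemiology (see above).
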