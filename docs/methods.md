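# Methods

## Model

Adult body weight is treated as a sex-specific allometric power law in
age and height, `W = c·A^x·H^y` with `c = exp(a + b·G)` and the sex
dummy `G` (men 1, women 0).  All fitting happens on the natural-log
scale, `ln W = a + x ln A + y ln H + b G`, by ordinary least squares
(statsmodels, QR-based; a test pins the solution to a reference
`numpy.linalg.lstsq` solve at 1e-10).  The model space is exactly
{ln A, ln H, G}: no interactions, no further covariates, no robust or
quantile variants.

Stepwise selection follows the classical forward-entry /
backward-removal recipe with entry p ≤ 0.05 and removal p ≥ 0.10 —
the conventional defaults of the era's statistical software; both
thresholds are arguments.  A term that is not selected has coefficient
exactly 0 in the stored coefficient set, so predictions and selection
are always consistent.

The corrected weight is the ratio `WC = W / WP` of measured to
model-predicted weight.  If the log-scale error is symmetric around 0,
`ln WC` is centred at 0, WC is centred near 1, and WC is independent of
the model covariates — which is what the validation protocol tests.

Units are strict throughout: years, metres, kilograms, natural logs.
Heights above 3 m are rejected with a hint about centimetre input
(an explicit `convert_cm` flag divides by 100); ages must lie in a
configurable plausible window, default 18–79, the reference inclusion
range.  Sex tokens accepted on input: M/F/male/female/1/0
(case-insensitive), with 1 mapping to male to match the dummy coding.

## Reference threshold

The overweight cutoff is the empirical 97.5th percentile of WC in a
healthy reference sample.  The quantile estimator interpolates linearly
at rank h = (n+1)p on the sorted sample, clamped to the extremes
(numpy's "weibull" rule) — the same estimator is used for all IQRs so
summaries and thresholds are mutually consistent; the rule name is
recorded in every `ThresholdSpec`.  The symmetric 2.5th-percentile lower
bound is computed and reported but never used for classification, since
only the upper criterion is defined.  Below 40 observations the 2.5%
tail is too unstable to trust and a warning is logged.

Classification conventions differ deliberately between the two criteria
and are kept verbatim: WC is overweight strictly above the cutoff
(the boundary value is normal), BMI is overweight at or above its
cutoff (default 25.0 kg/m²).  The published cutoff is applied at
exactly 1.1440 as printed; internally derived cutoffs keep full
precision.  Whether the original cutoff was computed from rounded or
full-precision WC values is unknowable from the printed record; full
precision is assumed here.

## Statistical procedures

Five tests are implemented, each with a fixed, documented switchover
between an exact small-sample method and a classical approximation
(all switchover points are overridable arguments):

| test | exact when | otherwise |
|---|---|---|
| Spearman | n ≤ 10 (full permutation) | t approximation |
| Mann–Whitney | nA+nB ≤ 12 (labeling enumeration, midranks) | normal approx., tie + continuity correction |
| Wilcoxon signed-rank | n ≤ 15 (sign enumeration) | normal approx., continuity correction |
| binomial | always exact | — |
| McNemar | b+c < 25 (binomial form) | chi-square with continuity correction |

Two-sided p-values for the discrete exact tests use the doubled smaller
tail, capped at 1 — simpler and more reproducible than the
minimum-likelihood convention, and recorded in every result.  Ties are
midranked everywhere; zero differences in the signed-rank test are
dropped (the classical treatment) with the count logged.  Each exact
path is verified in the test suite against an independent brute-force
enumeration written from the textbook definitions, and null simulations
check that all five reject at the 5% level at a rate within
[0.03, 0.07].

## Validation protocol

The reference workflow splits a healthy cohort 7:3 into a development
subgroup (fit + threshold) and a verification subgroup.  The original
account states the split "ensured" covariate balance without giving a
mechanism; here balance is enforced by re-randomization: draw a split,
test age/height/weight/BMI by Mann–Whitney and the sex ratio by a
two-proportion z-test, and redraw (bounded attempts, recorded) if any
p < 0.05.

On the verification subgroup, three conditions are tested at α = 0.05
(no multiple-testing correction, matching the original protocol):

1. *Location*: WC centred at 1, operationalized as a non-significant
   Wilcoxon signed-rank test of ln WC against 0.  The nonparametric
   operationalization fits a protocol that reports medians and uses
   rank tests throughout; the raw median and IQR are also reported.
2. *Association*: Spearman WC-vs-W significant with rho > 0.
3. *Independence*: Spearman WC-vs-age and WC-vs-height both
   non-significant, and no sex difference by Mann–Whitney.

Note an inherent operating characteristic of this design: conditions 1
and 3 stack four independent 5%-level no-rejection requirements, so
even a perfectly specified model passes all three conditions in only
about 0.95⁴ ≈ 81% of replicates (estimation error in the development-
subgroup coefficients pushes it a little lower; simulations here
measure ≈ 70–75% at n = 1224).  A single failed replicate is therefore
expected behaviour of the protocol, not evidence against the model.

## Screening comparison

Both criteria are read as screens for each cardiometabolic label
(positive = overweight).  Per disease and stratum (total/male/female)
the package reports sensitivity, specificity and accuracy, plus McNemar
tests computed on paired per-subject outcomes — accuracy on correctness
pairs over all subjects, sensitivity on the diseased subset, specificity
on the healthy subset (the standard paired-screen comparison; the
source analysis does not spell the pairing out).  Percentages are
presented to one decimal; full precision is retained internally.
Reclassification summaries require every input subject to meet the BMI
criterion and report counts and rates overall and by sex.

## Synthetic cohorts

The generator emulates the printed structure of the reference
population, not real anthropometric covariance:

* sex ~ Bernoulli(0.5);
* age ~ uniform on [18, 79] — the inclusion window; this reproduces the
  printed median (46) and IQR (≈27) to a good approximation and is the
  deliberate default (pluggable in principle via the params object);
* height ~ per-sex normal, means 1.71 / 1.60 m, SD 0.052 m
  (= printed IQR 0.07 / 1.349 under normality), truncated to
  (1.2, 2.2) m; sex is the only height covariate — no height–age trend
  is modelled because none is reported;
* ln W = a + x ln A + y ln H + bG + ε, ε ~ N(0, σ²), published
  coefficients by default.

The residual SD σ is the one quantity the printed record does not pin
down.  `calibrate_sigma` recovers it from the reported fit quality:
with signal variance V of the linear predictor (estimated by large-n
Monte Carlo), σ = sqrt(V(1−R²)/R²) at the target adjusted R² of 0.6634,
giving σ ≈ 0.081; refitting on cohorts generated at that σ lands the
adjusted R² within a few hundredths of the target.  The plain default
`residual_sd = 0.1` is a round value in the same regime used where an
uncalibrated noise level suffices (e.g. exponent-recovery simulations).
At σ ≈ 0.081 the implied 97.5th WC percentile is exp(1.96σ) ≈ 1.17,
close to but above the published 1.1440 — the real reference
distribution is slightly tighter-tailed than lognormal, one of several
features (age structure, secular height trends, measurement rounding)
the generator does not emulate.  Passing tests on these cohorts
demonstrate the correctness of the algorithms under the stated model,
not demographic fidelity.

Overweight-type cohorts multiply generated weights by an inflation
factor (scalar or distribution, support ≥ 1) and keep only subjects
with BMI ≥ 25, optionally to per-sex quotas; the generator aborts if
the acceptance rate falls below 1%.  Disease labels are Bernoulli with
logistic probability in WC; `tune_intercepts` root-finds the intercepts
that hit target marginal prevalences (e.g. the reference trial's
241/659/272/262 out of 1219) for given slopes.

All generators are pure functions of (params, seed); a single seed is
expanded into independent sub-streams via
`SeedSequence(seed, spawn_key=(stream,))` with fixed stream ids, so new
streams never perturb existing ones.

## Problem sizes and numerical choices

Simulation-based tests use the sizes the protocol itself names
(n = 1224 with an 857/367 split; 10,000-subject recovery cohorts;
100–1,000 replicates for rate estimates; 200 replicates for the
end-to-end operating characteristic).  Exponent-recovery assertions are
made on the mean over 25 replicates because the single-fit sampling SD
of the height exponent (~0.03, driven by the ~3% within-sex height CV)
exceeds the ±0.02 recovery band being checked.  Exact-test enumeration
bounds (10/12/15/25) keep worst-case enumeration under ~4 million
permutations.  Degenerate inputs (zero-variance index, all-zero
differences, no discordant pairs, empty strata) return explicit
not-computable statuses rather than NaN surprises, and every boundary
rule (WC strict, BMI inclusive) has a dedicated test.

## Known limitations

* The generator's lognormal residual makes its WC tail slightly heavier
  than the real reference distribution (see above); derived thresholds
  on synthetic cohorts are therefore a little above 1.1440.
* The published coefficients are for healthy Chinese Han adults;
  nothing here addresses transport to other populations.
* One row = one subject: no longitudinal support, no imputation.
* The exact Spearman path enumerates n! permutations and is intentionally
  capped at n = 10.
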