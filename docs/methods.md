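# Methods

## Problem setting

Uncomplicated hypertension (UH) in pregnancy — gestational hypertension or
worsening of essential hypertension beyond the 20th gestational week,
defined by office BP ≥ 140 and/or ≥ 90 mmHg — is common and worsens
maternal and fetal prognosis, yet no single early biomarker predicts it
well. The package implements an early-risk analysis that combines first
trimester 24-h ambulatory blood-pressure (ABPM) indices with serum uric
acid (UA) and the angiogenic imbalance ratio sFlt-1/PlGF (AF), in four
stages:

1. baseline descriptives (median/IQR + Mann-Whitney for continuous
   variables; count/percent + chi-square or Fisher for binary ones, plus
   nocturnal dipping, 100·(day − night)/day);
2. the **UA-AF index**: a degree-selected polynomial-logit combination of
   (UA, AF), carried forward as each subject's *out-of-fold* logit;
3. multivariate logistic risk models per BP index (± the UA-AF index),
   with change-in-estimate confounder screening, Wald/odds-ratio tables,
   omnibus LRT, Hosmer-Lemeshow calibration, Nagelkerke R², and ROC/AUC
   with the Hanley-McNeil standard error;
4. Bayesian Beta-Binomial comparison of two models' classification
   accuracies.

Because the motivating cohort (132 pregnancies, 72 UH cases) is not
publicly deposited, the package ships a synthetic-cohort generator whose
defaults emulate that cohort's published marginals and outcome structure;
all statistical properties are demonstrated on it.

## Synthetic cohort generator

**Continuous marginals.** Variables are drawn through a Gaussian copula.
Age, BMI, heart rate and all BP indices are truncated normal; UA, sFlt-1
and PlGF are lognormal (their published IQRs are comparable to or larger
than the medians, the signature of heavy right skew). Location/scale are
back-solved from median *m* and IQR *r*:

- normal: μ = m, σ = r / (2·z₀.₇₅) with z₀.₇₅ ≈ 0.6745;
- lognormal: μ = ln m, σ = asinh(r / 2m) / z₀.₇₅
  (from IQR = 2m·sinh(z₀.₇₅σ)).

Defaults reproduce the published cohort's medians (age 36 y, BMI
30.8 kg/m², office BP 134.5/81 mmHg, UA 4.1 mg/dL, sFlt-1 1908 U/L,
PlGF 215.5 U/L). Day/night ABPM period medians (122/108 systolic,
77/64 diastolic mmHg) are plausible clinic values chosen by us — the
source tables do not print them — and the 24-h indices are derived as the
day-weighted mix (2·day + night)/3, reflecting the roughly 2:1 ratio of
daytime to nighttime readings. One structural limitation: with both
marker medians matched, the implied sFlt-1/PlGF ratio median is
1908/215.5 ≈ 8.85 (the log-ratio median is the difference of log medians
regardless of correlation), somewhat above the published 7.0; we match
the directly measured markers and accept the derived discrepancy.

**Copula correlations** default to a physiologically sensible block
(BP indices mutually r = 0.4–0.7, BMI-BP ≈ 0.2–0.3, BMI-UA 0.3,
sFlt-1-PlGF 0.3, rest 0) and are fully configurable; the matrix is
validated for positive definiteness.

**Binary covariates** use the published prevalences; antihypertensive
treatment is drawn conditionally on essential hypertension (drugs ⊂ HT).
Essential hypertension additionally shifts all BP indices (+6/+4 mmHg
systolic/diastolic by default), with the unconditional location re-centred
so overall medians still match.

**Outcome model.** UH is Bernoulli with logit

η = β₀ + β_nSBP·(nSBP − 108) + s(u, a) + Σ γ_c·c,

where u, a are the *standardized log-scale* biomarkers (exact standard
normals by construction), s is a polynomial surface, and c ranges over
binary covariates. Defaults: β_nSBP = 0.098 per mmHg (the published
fitted effect); γ = 1.0 / 1.3 / 0.4 for former smoking / HT drugs /
essential HT; s contains only the second-order terms of the published
index equation (−0.9713 u², +1.4606 u·a, −0.3904 a²) with linear terms
zero. A pure-quadratic surface in jointly normal inputs is uncorrelated
with each input, so neither biomarker shows a first-order association
with UH (the published baseline table reports p = 0.46 / 0.54 for UA and
the ratio) while a degree-2 model has real signal — at n = 132 the
cross-validated degree-2 accuracy lands in the high 0.6s, matching the
published sweep. β₀ is solved by root-finding on a fixed-seed reference
sample of 20 000 draws so the expected prevalence equals 72/132; it
depends only on the configuration, never on the cohort seed.

A `night_shift_mmhg` knob can add mmHg to cases' nighttime indices after
the outcome draw (attenuated dipping); it defaults to 0 so the outcome
model remains exactly the logistic form above, which the
parameter-recovery tests rely on.

**What the generator does not emulate:** longitudinal BP trajectories,
gestational-age dynamics, measurement error and device effects,
missingness, or progression to preeclampsia. Passing tests therefore
demonstrate correctness of the *procedures* under a known generating
mechanism, not clinical performance on real cohorts.

## Descriptive conventions

Quartiles use linear interpolation between order statistics (Hyndman-Fan
type 7, numpy's default); the choice is fixed so IQRs are reproducible.
Pearson chi-square is computed *without* continuity correction — the
published HT-drugs p = 0.005 is reproduced from its 2×2 counts only under
that convention — with Fisher's exact two-sided test whenever any
expected cell is < 5. The Mann-Whitney p uses the tie- and
continuity-corrected normal approximation; for combined n ≤ 10 the null
distribution is enumerated exactly (the approximation then agrees with
enumeration to ≤ 0.02, which the corrected form achieves and the
uncorrected form does not).

## UA-AF index

Inputs are standardized (training-fold mean/SD) before expansion; the AF
ratio is log-transformed first by default (it is lognormal to good
approximation), UA is not (mild skew). Both transforms are configurable —
the published equation's provenance on this point is ambiguous, and its
coefficient magnitudes are only plausible on a standardized scale. The
inner logistic fit uses L2 regularization at scikit-learn's common
default strength (C = 1.0), with an unregularized option.

Fold assignment is deterministic and keyed by (subject id, seed) hashes
ranked within outcome class: row order can never change a subject's fold,
and class proportions per fold are preserved within one subject. The
degree sweep averages metrics over **5 repeats** of stratified 5-fold CV:
at n = 132 a single 5-fold split leaves between-degree test-accuracy
differences (~0.02–0.05) inside fold-assignment noise, and repeat
averaging is the standard variance-reduction remedy. Accuracy inside CV
uses the 0.5 probability threshold.

Degree selection: among degrees whose train − test accuracy gap is
≤ 0.05, take the lowest degree within 0.02 of the best test accuracy
(ties to the lower degree); if no degree satisfies the gap constraint the
rule is applied to all. On the published sweep's printed metrics this
returns degree 2.

The fitted index stores (a) per-subject out-of-fold logits — each
produced by the fold model that excluded that subject, eliminating
in-sample leakage when the index is reused as a predictor — and (b) a
full-data equation (scaling + coefficients) for scoring external data.

## Risk models

Maximum-likelihood logistic regression (Newton-Raphson, 100 iterations,
tolerance 1e-10) with SEs from the inverse observed information. Perfect
or quasi-complete separation raises a convergence error rather than
returning divergent estimates; rank-deficient designs raise an error
naming the collinear columns (QR with pivoting). Odds-ratio CIs are Wald
with z = 1.96. Confounders are retained by the ≥ 10% change-in-estimate
rule on the exposure's odds-ratio scale; note the rule is scale-dependent
(a per-mmHg OR near 1.05 can hardly move 10% — screening an exposure on a
per-SD scale is more sensitive). Interaction terms are screened by Wald
p < 0.05.

Hosmer-Lemeshow uses g = 10 risk-ordered near-equal groups (remainder to
the highest-risk groups; tied probabilities stay together; degenerate
expected cells trigger an upward merge with a warning), df = g − 2. The
df = g − 2 reference distribution presumes *fitted* probabilities; fed
true generating probabilities the test over-rejects by construction.
AUC is trapezoidal over all thresholds (equal to pairwise concordance
with ties counted ½); its SE is Hanley-McNeil with the exponential
approximation Q₁ = A/(2−A), Q₂ = 2A²/(1+A), which reproduces the
magnitude of the published SEs (0.032–0.044) at 60/72 cases.
Reported model accuracy is in-sample at threshold 0.5 and therefore
optimistically biased — mirroring the reporting convention of the
analysis it reproduces, which states the same limitation.

## Bayesian accuracy comparison

Each accuracy is a binomial proportion with a Beta(1,1) prior; k correct
out of n gives Beta(1+k, 1+n−k). When only a rounded accuracy is
reported, k = round(accuracy·n) (halves away from zero), and an optional
sensitivity report re-runs the comparison at k ± 1 (for the reference
cases this moves P(θ₁ > θ₀) by < 0.01). P(θ₁ > θ₀) and the difference CI
use 100 000 Monte-Carlo draws per posterior from a seeded generator;
per-accuracy CIs use exact Beta quantiles (less noise at identical
target). The treatment assumes the two accuracy counts are independent
binomials, ignoring that both models score the same subjects.

## Problem sizes in the test suite

Marginal fidelity and parameter recovery use n = 5000 cohorts (50
replicates for the β_nSBP Wald-coverage check); degree-selection and
index-adds-AUC properties use 25 replicates at the study size n = 132;
Hosmer-Lemeshow type-I calibration uses 200 replicates at n = 2000;
Monte-Carlo-vs-quadrature checks run at the analysis's own 100 000 draws.
These sizes give the binomial/Monte-Carlo error margins the assertions
state while keeping the full suite in a few minutes on one core.

## Known limitations

- The published index equation cannot be reproduced coefficient-for-
  coefficient: whether the original inputs were log-transformed,
  standardized, or the fit regularized is not recoverable from the
  report; both choices are exposed as configuration.
- Printed Wald statistics in the source tables reflect unrounded B/SE
  and are not exactly reconstructible from the printed values.
- Real-cohort AUC/accuracy values are not reproducible without the
  undeposited data; the package demonstrates the qualitative pattern
  (nighttime indices + index outperform office-only models) on synthetic
  cohorts instead.
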