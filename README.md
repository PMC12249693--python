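# uhrisk

Early-pregnancy risk modelling for **uncomplicated hypertension (UH)** —
gestational hypertension or worsening of essential hypertension beyond the
20th gestational week (office BP ≥ 140 and/or ≥ 90 mmHg). The package is
aimed at biostatisticians and clinical researchers working with first
trimester 24-h ambulatory blood-pressure monitoring (ABPM) and angiogenic
biomarkers, and provides a tested, reusable implementation of the full
analysis chain:

- **`uhrisk.cohort`** — a synthetic-cohort generator (Gaussian copula,
  lognormal biomarkers, logistic outcome model) emulating a 132-pregnancy
  cardiovascular-risk cohort, so every downstream stage is testable
  without patient data;
- **`uhrisk.descriptives`** — baseline tables (median/IQR + Mann-Whitney;
  count/percent + chi-square or Fisher) and nocturnal dipping,
  100·(day − night)/day;
- **`uhrisk.index`** — the **UA-AF index**: serum uric acid (UA) and the
  sFlt-1/PlGF ratio (AF) are standardized, expanded into a polynomial of
  cross-validation-selected degree, and combined by a logistic model; each
  subject's index value is the **out-of-fold logit** from the fold that
  excluded them, so reusing it as a predictor leaks no in-sample
  information;
- **`uhrisk.logistic`** — multivariate logistic risk models per BP index
  (± the UA-AF index) with change-in-estimate confounder screening
  (≥ 10% odds-ratio shift), Wald odds-ratio tables, omnibus LRT,
  Hosmer-Lemeshow calibration, Nagelkerke R², and ROC/AUC with the
  Hanley-McNeil standard error;
- **`uhrisk.bayes`** — Bayesian comparison of two models' classification
  accuracies: Beta(1,1) priors, conjugate Beta-Binomial updates
  Beta(1+k, 1+n−k), and the Monte-Carlo posterior probability
  P(θ₁ > θ₀) with 95% credible intervals for each accuracy and their
  difference;
- **`uhrisk.cli`** — a `uhrisk` command with subcommands `simulate`,
  `describe`, `index`, `fit`, `compare` and `run` (the full pipeline,
  deterministic under a fixed master seed).

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Compare a nighttime-SBP + UA-AF-index model (accuracy 0.83) against an
office-SBP model (accuracy 0.69), both evaluated on the same 132
pregnancies:

```sh
$ uhrisk compare --acc1 0.83 --acc0 0.69 --n 132 --seed 2
{
  "p_superior": 0.99703,
  "ci_1": [0.7603, 0.8871],
  "ci_0": [0.6058, 0.7620],
  "ci_diff": [0.0411, 0.2428],
  "n_draws": 100000,
  "seed": 2,
  "mc_se": 0.00017
}
```

Reading: with uniform priors, 0.83·132 ≈ 110 and 0.69·132 ≈ 91 correct
predictions give posteriors Beta(111, 23) and Beta(92, 42). The posterior
probability that the nighttime model is genuinely more accurate is
≈ 0.997; its accuracy lies in [0.760, 0.887] with 95% probability, and the
accuracy difference in [0.041, 0.243] — an interval that excludes zero.

The full pipeline on a synthetic cohort:

```sh
$ uhrisk run --seed 1 --out bundle/
{
  "selected_degree": 2,
  "accuracies": {
    "office_sbp": 0.583, "office_sbp_uaaf": 0.727,
    "nsbp": 0.598,       "nsbp_uaaf": 0.75,
    "office_dbp": 0.576, "office_dbp_uaaf": 0.742,
    "ndbp": 0.576,       "ndbp_uaaf": 0.75
  },
  "comparisons": {
    "nsbp_uaaf_vs_office_sbp": 0.998,
    "ndbp_uaaf_vs_office_dbp": 0.999
  }
}
```

The cross-validated degree sweep picks the quadratic transformation (the
cohort's generating biomarker surface is quadratic, so this is the right
answer); models that add the UA-AF index outperform their BP-only
counterparts, and the Bayesian comparison gives high posterior probability
that the nighttime-BP + index models beat the office-BP baselines. The
bundle directory holds the cohort CSV, baseline table, per-degree CV
metrics, one coefficient table and ROC CSV per model, comparison JSON and
a manifest of seeds.

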