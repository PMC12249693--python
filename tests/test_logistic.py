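"""Logistic risk models: fit, screening rules, diagnostics, ROC."""

import numpy as np
import pandas as pd
import pytest

from uhrisk import (
    CohortConfig,
    ConvergenceError,
    RankDeficiencyError,
    classification_accuracy,
    diagnostics,
    fit_logistic,
    generate_cohort,
    hosmer_lemeshow,
    nagelkerke_r2,
    omnibus_lrt,
    roc_auc,
    screen_confounders,
    screen_interactions,
)


def simulate_logit(n, betas, seed, intercept=-0.2):
    """Gaussian predictors, logistic outcome with known coefficients."""
    rng = np.random.default_rng(seed)
    x = pd.DataFrame({f"x{i}": rng.normal(0, 1, n)
                      for i in range(len(betas))})
    eta = intercept + x.to_numpy() @ np.asarray(betas)
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return x, y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.repeat([True, False], [72, 60])
        fit = fit_logistic(pd.DataFrame(index=range(132)), y)
        assert fit.coefficient("const") == pytest.approx(np.log(72 / 60),
                                                         abs=1e-8)

    def test_odds_ratio_and_ci_reconstruction(self):
        """Exp(B) and Wald CI follow from B and SE exactly."""
        x, y = simulate_logit(500, [0.8], seed=1)
        fit = fit_logistic(x, y)
        i = fit.names.index("x0")
        assert fit.odds_ratios[i] == pytest.approx(np.exp(fit.params[i]))
        lo, hi = fit.or_ci[i]
        assert lo == pytest.approx(np.exp(fit.params[i] - 1.959964 * fit.bse[i]))
        assert hi == pytest.approx(np.exp(fit.params[i] + 1.959964 * fit.bse[i]))
        assert lo <= fit.odds_ratios[i] <= hi

    def test_parameter_recovery_large_n(self):
        x, y = simulate_logit(5000, [0.7, -0.4], seed=2)
        fit = fit_logistic(x, y)
        for name, true in (("x0", 0.7), ("x1", -0.4)):
            i = fit.names.index(name)
            assert abs(fit.params[i] - true) < 3 * fit.bse[i]

    def test_perfect_separation_raises(self):
        x = pd.DataFrame({"x": np.linspace(-2, 2, 40)})
        y = x.x > 0
        with pytest.raises(ConvergenceError):
            fit_logistic(x, y)

    def test_rank_deficiency_names_columns(self):
        x, y = simulate_logit(200, [0.5], seed=3)
        x["x0_copy"] = x.x0 * 2.0
        with pytest.raises(RankDeficiencyError, match="x0"):
            fit_logistic(x, y)

    def test_missing_values_rejected(self):
        x, y = simulate_logit(50, [0.5], seed=4)
        x.loc[3, "x0"] = np.nan
        with pytest.raises(ValueError):
            fit_logistic(x, y)

    def test_summary_table_layout(self):
        x, y = simulate_logit(300, [0.5], seed=5)
        table = fit_logistic(x, y).summary_table()
        assert list(table.columns) == ["Variable", "B", "SE", "Wald",
                                       "p-Value", "Exp(B)", "95%CI Lower",
                                       "95%CI Upper"]


class TestOmnibus:
    def test_null_model(self):
        y = np.repeat([True, False], [40, 60])
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        stat, df, p = omnibus_lrt(fit)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert df == 0 and p == 1.0

    def test_strong_predictor_significant(self):
        x, y = simulate_logit(400, [2.5], seed=6)
        _, _, p = omnibus_lrt(fit_logistic(x, y))
        assert p < 1e-3

    def test_additivity_over_nested_models(self):
        x, y = simulate_logit(400, [0.6, 0.4], seed=7)
        fit1 = fit_logistic(x[["x0"]], y)
        fit12 = fit_logistic(x, y)
        stat12, _, _ = omnibus_lrt(fit12)
        stat1, _, _ = omnibus_lrt(fit1)
        step = 2.0 * (fit12.llf - fit1.llf)
        assert stat12 == pytest.approx(stat1 + step, abs=1e-8)


class TestNagelkerke:
    def test_null_model_zero(self):
        y = np.repeat([True, False], [30, 30])
        fit = fit_logistic(pd.DataFrame(index=range(60)), y)
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_brute_force_likelihood_oracle(self):
        x = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        y = np.array([False, False, True, False, True, True])
        fit = fit_logistic(x, y)
        p = fit.fitted
        ll = float(np.sum(np.where(y, np.log(p), np.log1p(-p))))
        p0 = y.mean()
        ll0 = float(np.sum(np.where(y, np.log(p0), np.log1p(-p0))))
        n = len(y)
        r2_cs = 1 - np.exp(2 * (ll0 - ll) / n)
        expected = r2_cs / (1 - np.exp(2 * ll0 / n))
        assert nagelkerke_r2(fit) == pytest.approx(expected, abs=1e-10)

    def test_rescaling_invariance(self):
        x, y = simulate_logit(300, [0.8], seed=8)
        r2_raw = nagelkerke_r2(fit_logistic(x, y))
        r2_scaled = nagelkerke_r2(fit_logistic(x * 37.5, y))
        assert r2_raw == pytest.approx(r2_scaled, abs=1e-8)

    def test_near_separation_approaches_one(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame({"x": np.r_[rng.normal(-3, 0.5, 50),
                                     rng.normal(3, 0.5, 50)]})
        y = np.repeat([False, True], 50)
        # tiny label noise keeps the MLE finite
        y[0], y[-1] = True, False
        assert nagelkerke_r2(fit_logistic(x, y)) > 0.8


class TestHosmerLemeshow:
    def test_flat_probabilities_zero_statistic(self):
        """All-tied probabilities collapse into one group; with the
        prevalence as the common value the statistic vanishes."""
        y = np.repeat([True, False], [30, 70])
        p = np.full(100, 0.3)
        stat, _, _ = hosmer_lemeshow(p, y, 10)
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_miscalibration_detected(self):
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(20):
            eta = rng.normal(0, 1.2, 2000)
            y = rng.random(2000) < 1 / (1 + np.exp(-eta))
            shifted = 1 / (1 + np.exp(-(eta + 1.0)))
            _, _, p = hosmer_lemeshow(shifted, y, 10)
            rejections += p < 0.05
        assert rejections > 16

    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.05, 0.95, 200)
        y = rng.random(200) < p
        _, df, _ = hosmer_lemeshow(p, y, 8)
        assert df == 6

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0, 0.5] * 20, [0, 1] * 20, 2)


def _auc_oracle(scores, outcomes):
    """O(n^2) pairwise concordance with ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 20, 120).astype(float)  # ties on purpose
        y = rng.random(120) < 0.5
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        roc = roc_auc(scores, y)
        assert roc.auc == pytest.approx(_auc_oracle(scores, y), abs=1e-12)

    def test_curve_monotone_and_ci_contains_auc(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(0, 1, 200) + np.repeat([0.0, 1.0], 100)
        y = np.repeat([False, True], 100)
        roc = roc_auc(scores, y)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.ci[0] <= roc.auc <= roc.ci[1]
        assert 0 <= roc.auc <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestClassificationAccuracy:
    def test_perfect_and_inverted(self):
        y = np.array([0, 1, 1, 0], dtype=bool)
        assert classification_accuracy(y.astype(float), y) == 1.0
        assert classification_accuracy(1.0 - y.astype(float), y) == 0.0

    def test_110_of_132(self):
        y = np.zeros(132, dtype=bool)
        p = np.where(np.arange(132) < 110, 0.1, 0.9)  # 110 correct
        assert classification_accuracy(p, y) == pytest.approx(0.8333, abs=5e-5)


class TestScreenConfounders:
    def test_null_candidate_not_retained(self):
        cfg = CohortConfig(n_subjects=4000, seed=13, surface={},
                           binary_outcome_effects={})
        df = generate_cohort(cfg)
        df["dm"] = df.dm.astype(float)
        out = screen_confounders(df, "sbp_night", "uh", ["dm"])
        assert (out.status == "dropped").all()
        assert (out.relative_change < 0.10).all()

    def test_common_cause_retained(self):
        """A covariate that raises both nighttime SBP and UH risk shifts
        the per-SD exposure odds ratio by well over 10%."""
        cfg = CohortConfig(
            n_subjects=4000, seed=14, surface={}, beta_nsbp=0.05,
            binary_outcome_effects={"essential_ht": 1.5},
            bp_shifts={"essential_ht": {"sbp_night": 20.0}},
        )
        df = generate_cohort(cfg)
        df["essential_ht"] = df.essential_ht.astype(float)
        df["nsbp_z"] = ((df.sbp_night - df.sbp_night.mean())
                        / df.sbp_night.std())
        out = screen_confounders(df, "nsbp_z", "uh", ["essential_ht"])
        assert (out.status == "retained").all()
        assert (out.relative_change > 0.10).all()


class TestScreenInteractions:
    def test_empty_candidates(self, cohort132):
        out = screen_interactions(cohort132.assign(
            a=cohort132.age, b=cohort132.bmi), "uh", [])
        assert out.empty

    def test_type_one_error_calibrated(self):
        hits = 0
        for seed in range(60):
            x, y = simulate_logit(400, [0.5, 0.5], seed=100 + seed)
            frame = x.assign(uh=y)
            out = screen_interactions(frame, "uh", [("x0", "x1")])
            hits += int(out.relevant.iloc[0])
        assert hits / 60 < 0.15

    def test_strong_interaction_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            x0, x1 = rng.normal(0, 1, 500), rng.normal(0, 1, 500)
            eta = 0.2 * x0 + 0.2 * x1 + 1.0 * x0 * x1
            y = rng.random(500) < 1 / (1 + np.exp(-eta))
            frame = pd.DataFrame({"x0": x0, "x1": x1, "uh": y})
            out = screen_interactions(frame, "uh", [("x0", "x1")])
            hits += int(out.relevant.iloc[0])
        assert hits / 20 > 0.8


class TestDiagnosticsBundle:
    def test_well_specified_model_passes_both(self):
        x, y = simulate_logit(1000, [0.8, -0.5], seed=15)
        diag = diagnostics(fit_logistic(x, y))
        assert diag.omnibus_p < 0.001   # real signal
        assert diag.hl_p > 0.01         # calibrated fit
        assert diag.hl_df == diag.hl_groups - 2
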