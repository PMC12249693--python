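"""Binary logistic risk models with the diagnostics clinicians report.

Thin, opinionated layer over ``statsmodels`` maximum-likelihood logistic
regression that packages the usual clinical-epidemiology report: Wald
statistics and odds ratios with 95% CIs, the omnibus likelihood-ratio test,
the Hosmer-Lemeshow calibration test, Nagelkerke's max-rescaled pseudo-R2,
ROC/AUC with the Hanley-McNeil standard error, plus confounder and
interaction screening rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr

from .exceptions import ConvergenceError, RankDeficiencyError

__all__ = [
    "LogisticFit",
    "ModelDiagnostics",
    "ROCCurve",
    "fit_logistic",
    "screen_confounders",
    "screen_interactions",
    "omnibus_lrt",
    "hosmer_lemeshow",
    "nagelkerke_r2",
    "roc_auc",
    "classification_accuracy",
]

_Z95 = 1.959963984540054


@dataclass
class LogisticFit:
    """A fitted logistic model and its Table-style report ingredients."""

    names: list[str]
    params: np.ndarray        # B, logit units (intercept last, named "const")
    bse: np.ndarray           # SE
    llf: float
    llnull: float
    n: int
    fitted: np.ndarray        # in-sample probabilities
    outcome: np.ndarray
    design: pd.DataFrame = field(repr=False, default=None)

    @property
    def wald(self) -> np.ndarray:
        return (self.params / self.bse) ** 2

    @property
    def p_values(self) -> np.ndarray:
        return stats.chi2.sf(self.wald, df=1)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def or_ci(self) -> np.ndarray:
        lo = np.exp(self.params - _Z95 * self.bse)
        hi = np.exp(self.params + _Z95 * self.bse)
        return np.column_stack([lo, hi])

    @property
    def accuracy(self) -> float:
        return classification_accuracy(self.fitted, self.outcome)

    @property
    def nagelkerke(self) -> float:
        return nagelkerke_r2(self)

    def coefficient(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def odds_ratio(self, name: str) -> float:
        return float(np.exp(self.coefficient(name)))

    def summary_table(self) -> pd.DataFrame:
        """Coefficient table with the conventional column layout."""
        ci = self.or_ci
        return pd.DataFrame({
            "Variable": self.names,
            "B": self.params,
            "SE": self.bse,
            "Wald": self.wald,
            "p-Value": self.p_values,
            "Exp(B)": self.odds_ratios,
            "95%CI Lower": ci[:, 0],
            "95%CI Upper": ci[:, 1],
        })


@dataclass
class ModelDiagnostics:
    """Omnibus LRT and Hosmer-Lemeshow results for one model."""

    omnibus_stat: float
    omnibus_df: int
    omnibus_p: float
    hl_stat: float
    hl_groups: int
    hl_df: int
    hl_p: float


@dataclass
class ROCCurve:
    """A threshold sweep with AUC, Hanley-McNeil SE, CI and test vs 0.5."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float
    ci: tuple[float, float]
    p_value: float


def _check_design(design: pd.DataFrame):
    x = design.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("design matrix contains missing values")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # QR with pivoting: the trailing pivots name the dependent columns.
        _, _, piv = qr(x, pivoting=True, mode="economic")
        bad = [design.columns[j] for j in piv[rank:]]
        raise RankDeficiencyError(sorted(map(str, bad)))
    return x


def fit_logistic(design: pd.DataFrame, outcome) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome.

    ``design`` holds the predictors (no constant column — one is appended
    and reported as ``const``).  SEs come from the inverse observed
    information.  Perfect separation and non-convergence raise
    ``ConvergenceError``; collinear predictors raise
    ``RankDeficiencyError`` naming the offending columns.
    """
    y = np.asarray(outcome, dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values")
    design = pd.DataFrame(design).astype(float)
    if len(design) != len(y):
        raise ValueError("design and outcome lengths differ")
    _check_design(design)
    x = sm.add_constant(design, prepend=False, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            model = sm.Logit(y, x)
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        except (np.linalg.LinAlgError, RuntimeWarning, sm.tools.sm_exceptions.PerfectSeparationError) as err:
            raise ConvergenceError(f"logistic fit failed: {err}") from err
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge in 100 iterations")
    bse = np.asarray(res.bse, dtype=float)
    if not np.isfinite(bse).all() or bse.max() > 1e4:
        raise ConvergenceError(
            "standard errors diverged (quasi-complete separation likely)"
        )
    return LogisticFit(
        names=list(x.columns),
        params=np.asarray(res.params, dtype=float),
        bse=bse,
        llf=float(res.llf),
        llnull=float(res.llnull),
        n=len(y),
        fitted=np.asarray(res.predict(), dtype=float),
        outcome=y.astype(bool),
        design=design,
    )


def omnibus_lrt(fit: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the model against intercept-only."""
    stat = max(2.0 * (fit.llf - fit.llnull), 0.0)
    df = len(fit.names) - 1
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return float(stat), df, p


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Max-rescaled Cox-Snell pseudo-R2, in [0, 1] (0 for the null model)."""
    n = fit.n
    r2_cs = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
    denom = 1.0 - np.exp(2.0 * fit.llnull / n)
    if denom <= 0:
        return 0.0
    return float(min(max(r2_cs / denom, 0.0), 1.0))


def hosmer_lemeshow(probabilities, outcomes, n_groups: int = 10):
    """Hosmer-Lemeshow calibration test over risk-ordered groups.

    Subjects are ranked by fitted probability into ``n_groups`` groups of
    near-equal size (ties stay together; remainder subjects go to the
    highest-risk groups).  Groups whose expected count in either outcome
    class is ~0 are merged upward with a warning.  df = groups - 2.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if p.size != y.size:
        raise ValueError("length mismatch")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    n = p.size
    if n < 2 * n_groups:
        raise ValueError("need at least two subjects per group")

    order = np.argsort(p, kind="stable")
    base = n // n_groups
    sizes = np.full(n_groups, base)
    sizes[n_groups - (n - base * n_groups):] += 1  # remainder to top risk
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    labels = np.empty(n, dtype=int)
    for g in range(n_groups):
        labels[order[bounds[g]:bounds[g + 1]]] = g
    # keep tied probabilities together: a tie run takes its top group label
    for v in np.unique(p):
        m = p == v
        if m.sum() > 1:
            labels[m] = labels[m].max()

    groups = []
    for g in range(n_groups):
        m = labels == g
        if m.sum() == 0:
            continue
        groups.append((int(m.sum()), float(p[m].sum()), int(y[m].sum())))
    # merge groups with degenerate expected counts into their neighbour
    merged = []
    for grp in groups:
        if merged and (min(merged[-1][1], merged[-1][0] - merged[-1][1]) < 1e-8):
            warnings.warn("merging Hosmer-Lemeshow group with empty expected cell")
            n0, e0, o0 = merged.pop()
            grp = (n0 + grp[0], e0 + grp[1], o0 + grp[2])
        merged.append(grp)

    stat = 0.0
    for size, expected1, observed1 in merged:
        expected0 = size - expected1
        stat += (observed1 - expected1) ** 2 / expected1
        stat += ((size - observed1) - expected0) ** 2 / expected0
    df = max(len(merged) - 2, 1)
    return float(stat), df, float(stats.chi2.sf(stat, df))


def roc_auc(scores, outcomes) -> ROCCurve:
    """ROC curve with trapezoidal AUC and the Hanley-McNeil SE.

    The trapezoidal AUC equals the concordance probability with ties
    counted one half.  SE uses the exponential approximation
    Q1 = A/(2-A), Q2 = 2A^2/(1+A); the CI is A +/- 1.96 SE truncated to
    [0, 1], and the p-value tests A = 0.5 by a two-sided normal test.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC needs both outcome classes")
    n1, n0 = int(y.sum()), int((~y).sum())

    # threshold sweep over unique scores, descending
    thresholds = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = s >= t
        tpr.append(float((pred & y).sum() / n1))
        fpr.append(float((pred & ~y).sum() / n0))
    fpr_arr, tpr_arr = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(auc - _Z95 * se, 0.0), min(auc + _Z95 * se, 1.0))
    if se == 0.0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    return ROCCurve(fpr_arr, tpr_arr, auc, se, ci, p)


def classification_accuracy(probabilities, outcomes, threshold: float = 0.5) -> float:
    """Fraction of subjects whose thresholded probability matches the outcome."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(outcomes, dtype=bool)
    return float(np.mean((p >= threshold) == y))


def screen_confounders(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    candidates: list[str],
    base_covariates: list[str] = (),
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Change-in-estimate confounder screen.

    A candidate is retained iff adding it to the base model changes the
    exposure's odds ratio by at least ``threshold`` in relative terms
    (|OR_adj - OR_crude| / OR_crude).  Candidates whose adjusted fit fails
    to converge are reported as undetermined rather than dropped.
    """
    y = cohort[outcome].astype(bool)
    base_cols = [exposure, *base_covariates]
    crude = fit_logistic(cohort[base_cols], y)
    or_crude = crude.odds_ratio(exposure)
    rows = []
    for cand in candidates:
        try:
            adj = fit_logistic(cohort[base_cols + [cand]], y)
        except ConvergenceError:
            rows.append((cand, np.nan, np.nan, "undetermined"))
            continue
        or_adj = adj.odds_ratio(exposure)
        change = abs(or_adj - or_crude) / or_crude
        rows.append((cand, or_adj, change,
                     "retained" if change >= threshold else "dropped"))
    return pd.DataFrame(rows, columns=["candidate", "or_adjusted",
                                       "relative_change", "status"]) \
        .assign(or_crude=or_crude)


def screen_interactions(
    cohort: pd.DataFrame,
    outcome: str,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wald screen of product terms: a pair is relevant if its product
    coefficient has p < alpha in a model with both main effects."""
    y = cohort[outcome].astype(bool)
    rows = []
    for a, b in pairs:
        design = cohort[[a, b]].astype(float).copy()
        prod = f"{a}:{b}"
        design[prod] = design[a] * design[b]
        fit = fit_logistic(design, y)
        i = fit.names.index(prod)
        p = float(fit.p_values[i])
        rows.append((a, b, float(fit.params[i]), p, p < alpha))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "coefficient",
                                       "p_value", "relevant"])


def diagnostics(fit: LogisticFit, n_groups: int = 10) -> ModelDiagnostics:
    """Bundle the omnibus LRT and Hosmer-Lemeshow test for one fit."""
    om_stat, om_df, om_p = omnibus_lrt(fit)
    hl_stat, hl_df, hl_p = hosmer_lemeshow(fit.fitted, fit.outcome, n_groups)
    return ModelDiagnostics(om_stat, om_df, om_p, hl_stat, n_groups, hl_df, hl_p)
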