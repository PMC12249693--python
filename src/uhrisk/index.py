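"""The UA-AF index: a cross-validated polynomial-logit biomarker combination.

Serum uric acid (UA) and the sFlt-1/PlGF angiogenic ratio (AF) often show no
first-order association with uncomplicated hypertension, yet carry joint
nonlinear signal.  The index captures it by

1. standardizing the two inputs (optionally after log-transforming the
   heavily skewed AF ratio) on the training data,
2. expanding them into all monomials ``ua**i * af**j`` with ``i + j <= d``,
3. fitting a logistic model on the expanded features, and
4. storing, for every subject, the *out-of-fold* linear predictor — the logit
   from the cross-validation fold model that never saw that subject — as the
   index value used downstream, avoiding in-sample leakage.

The polynomial degree is chosen by a stratified k-fold sweep over degrees
1-5, preferring the lowest degree that generalizes well without a large
train/test accuracy gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score

from .cohort import stratified_fold_of

__all__ = [
    "PolynomialSpec",
    "FeatureScaling",
    "CVMetrics",
    "IndexModel",
    "expand",
    "evaluate_index",
    "cv_degree_sweep",
    "select_degree",
    "build_index",
]


def _terms_for_degree(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (i, j), i + j <= degree, excluding the intercept (0, 0).

    Ordered by total degree, then by descending UA exponent, matching the
    conventional written form  ua, af, ua^2, ua*af, af^2, ...
    """
    return [(i, d - i) for d in range(1, degree + 1) for i in range(d, -1, -1)]


@dataclass(frozen=True)
class PolynomialSpec:
    """Degree and term list of a bivariate polynomial expansion."""

    degree: int
    terms: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        if not 1 <= self.degree <= 5:
            raise ValueError(f"degree must be in 1..5, got {self.degree}")
        if self.terms is None:
            object.__setattr__(self, "terms", tuple(_terms_for_degree(self.degree)))
        expected = (self.degree + 1) * (self.degree + 2) // 2 - 1
        if len(self.terms) != expected:
            raise ValueError(
                f"degree {self.degree} expects {expected} terms, "
                f"got {len(self.terms)}"
            )


@dataclass
class FeatureScaling:
    """Location/scale applied to (UA, AF) before polynomial expansion.

    ``log_af`` log-transforms the AF ratio first; ``log_ua`` likewise for
    uric acid (off by default — UA is only mildly skewed).
    """

    ua_mean: float = 0.0
    ua_sd: float = 1.0
    af_mean: float = 0.0
    af_sd: float = 1.0
    log_ua: bool = False
    log_af: bool = True

    @classmethod
    def fit(cls, ua_raw, af_raw, log_ua: bool = False, log_af: bool = True):
        ua = np.log(ua_raw) if log_ua else np.asarray(ua_raw, dtype=float)
        af = np.log(af_raw) if log_af else np.asarray(af_raw, dtype=float)
        return cls(float(np.mean(ua)), float(np.std(ua)) or 1.0,
                   float(np.mean(af)), float(np.std(af)) or 1.0,
                   log_ua, log_af)

    def transform(self, ua_raw, af_raw):
        ua = np.log(ua_raw) if self.log_ua else np.asarray(ua_raw, dtype=float)
        af = np.log(af_raw) if self.log_af else np.asarray(af_raw, dtype=float)
        return (ua - self.ua_mean) / self.ua_sd, (af - self.af_mean) / self.af_sd


@dataclass
class CVMetrics:
    """Fold-averaged metrics for one polynomial degree."""

    degree: int
    train_accuracy: float
    test_accuracy: float
    train_auc: float
    test_auc: float
    train_log_loss: float
    test_log_loss: float

    @property
    def gap(self) -> float:
        return self.train_accuracy - self.test_accuracy


@dataclass
class IndexModel:
    """A fitted UA-AF index.

    ``coefficients`` (intercept first, then one per spec term) and
    ``scaling`` describe the full-data equation used to score new subjects;
    ``oof_logits`` holds the leakage-free per-subject index values, and
    ``fold_of`` the fold that produced each of them.
    """

    spec: PolynomialSpec
    intercept: float
    coefficients: np.ndarray
    scaling: FeatureScaling
    oof_logits: pd.Series | None = None
    fold_of: pd.Series | None = None
    cv_metrics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "degree": self.spec.degree,
            "terms": [list(t) for t in self.spec.terms],
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "scaling": self.scaling.__dict__,
            "cv_metrics": {str(d): m.__dict__ for d, m in self.cv_metrics.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IndexModel":
        d = json.loads(text)
        return cls(
            spec=PolynomialSpec(d["degree"], tuple(map(tuple, d["terms"]))),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            scaling=FeatureScaling(**d["scaling"]),
            cv_metrics={int(k): CVMetrics(**v)
                        for k, v in d.get("cv_metrics", {}).items()},
        )


def expand(ua, af, spec: PolynomialSpec) -> np.ndarray:
    """Monomial features ``ua**i * af**j`` per spec term, columns in spec order."""
    ua = np.atleast_1d(np.asarray(ua, dtype=float))
    af = np.atleast_1d(np.asarray(af, dtype=float))
    if not (np.isfinite(ua).all() and np.isfinite(af).all()):
        raise ValueError("polynomial expansion needs finite inputs")
    return np.column_stack([ua**i * af**j for i, j in spec.terms])


def evaluate_index(ua_raw, af_raw, model: IndexModel) -> np.ndarray:
    """Score raw biomarker values with a fitted index (logit scale)."""
    if model.coefficients is None:
        raise RuntimeError("index model is not fitted")
    ua_z, af_z = model.scaling.transform(ua_raw, af_raw)
    features = expand(ua_z, af_z, model.spec)
    return model.intercept + features @ model.coefficients


def _fit_poly_logit(ua_z, af_z, y, spec, c_reg):
    features = expand(ua_z, af_z, spec)
    # c_reg is the inverse L2 strength; None means unregularized.
    clf = LogisticRegression(C=np.inf if c_reg is None else c_reg,
                             solver="lbfgs", max_iter=2000)
    clf.fit(features, np.asarray(y, dtype=int))
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def _score(intercept, coefs, ua_z, af_z, spec):
    return intercept + expand(ua_z, af_z, spec) @ coefs


def _check_cohort(cohort: pd.DataFrame):
    y = cohort["uh"].astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ValueError("cohort must contain both outcome classes")
    return y


def cv_degree_sweep(
    cohort: pd.DataFrame,
    degrees=range(1, 6),
    n_folds: int = 5,
    seed: int = 0,
    c_reg: float | None = 1.0,
    log_af: bool = True,
    n_repeats: int = 5,
) -> dict[int, CVMetrics]:
    """Repeated stratified k-fold sweep over polynomial degrees.

    Per degree, each fold fits scaling + expansion + logistic model on the
    training part only and scores both parts; the returned metrics are
    means over all folds of ``n_repeats`` independent fold assignments
    (repeats damp the fold-to-fold noise that otherwise dominates degree
    differences at clinical sample sizes).  Fold assignment is keyed by
    subject id and seed, so it is invariant to row order.
    """
    y = _check_cohort(cohort)
    if n_folds < 2:
        raise ValueError("need at least two folds")
    ua = cohort["uric_acid"].to_numpy(dtype=float)
    af = (cohort["sflt1"] / cohort["plgf"]).to_numpy(dtype=float)
    fold_sets = [stratified_fold_of(cohort["id"], y, n_folds, seed + 7919 * r)
                 for r in range(n_repeats)]

    out: dict[int, CVMetrics] = {}
    for degree in degrees:
        spec = PolynomialSpec(degree)
        rows = []
        for folds in fold_sets:
            for f in range(n_folds):
                tr, te = folds != f, folds == f
                if y[tr].all() or not y[tr].any() or te.sum() == 0:
                    continue
                scaling = FeatureScaling.fit(ua[tr], af[tr], log_af=log_af)
                ua_tr, af_tr = scaling.transform(ua[tr], af[tr])
                ua_te, af_te = scaling.transform(ua[te], af[te])
                b0, coefs = _fit_poly_logit(ua_tr, af_tr, y[tr], spec, c_reg)
                p_tr = expit(_score(b0, coefs, ua_tr, af_tr, spec))
                p_te = expit(_score(b0, coefs, ua_te, af_te, spec))
                rows.append((
                    float(np.mean((p_tr >= 0.5) == y[tr])),
                    float(np.mean((p_te >= 0.5) == y[te])),
                    _safe_auc(y[tr], p_tr),
                    _safe_auc(y[te], p_te),
                    float(log_loss(y[tr], p_tr, labels=[False, True])),
                    float(log_loss(y[te], p_te, labels=[False, True])),
                ))
        means = np.nanmean(np.asarray(rows, dtype=float), axis=0)
        out[degree] = CVMetrics(degree, *means)
    return out


def _safe_auc(y, p) -> float:
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, p))


def select_degree(
    metrics: dict[int, CVMetrics],
    accuracy_band: float = 0.02,
    max_gap: float = 0.05,
) -> int:
    """Pick the simplest degree that generalizes well.

    Among degrees whose train-test accuracy gap is at most ``max_gap``, the
    lowest degree within ``accuracy_band`` of the best test accuracy wins;
    ties break toward the lower degree.  If no degree satisfies the gap
    constraint, the rule is applied to all degrees.
    """
    if len(metrics) < 2:
        raise ValueError("need metrics for at least two degrees")
    admissible = [m for m in metrics.values() if m.gap <= max_gap]
    if not admissible:
        admissible = list(metrics.values())
    best = max(m.test_accuracy for m in admissible)
    candidates = [m.degree for m in admissible
                  if m.test_accuracy >= best - accuracy_band]
    return min(candidates)


def build_index(
    cohort: pd.DataFrame,
    degree: int,
    n_folds: int = 5,
    seed: int = 0,
    c_reg: float | None = 1.0,
    log_af: bool = True,
) -> IndexModel:
    """Fit the index: out-of-fold logits plus the full-data equation.

    Each subject's ``oof_logits`` entry is the linear predictor from the
    fold model that excluded that subject (fold recorded in ``fold_of``);
    the stored equation (scaling + coefficients) is refit on all subjects
    for scoring data outside the cohort.
    """
    y = _check_cohort(cohort)
    spec = PolynomialSpec(degree)
    folds = stratified_fold_of(cohort["id"], y, n_folds, seed)
    ua = cohort["uric_acid"].to_numpy(dtype=float)
    af = (cohort["sflt1"] / cohort["plgf"]).to_numpy(dtype=float)

    oof = np.full(len(cohort), np.nan)
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if te.sum() == 0:
            continue
        scaling = FeatureScaling.fit(ua[tr], af[tr], log_af=log_af)
        ua_tr, af_tr = scaling.transform(ua[tr], af[tr])
        ua_te, af_te = scaling.transform(ua[te], af[te])
        b0, coefs = _fit_poly_logit(ua_tr, af_tr, y[tr], spec, c_reg)
        oof[te] = _score(b0, coefs, ua_te, af_te, spec)

    full_scaling = FeatureScaling.fit(ua, af, log_af=log_af)
    ua_z, af_z = full_scaling.transform(ua, af)
    b0, coefs = _fit_poly_logit(ua_z, af_z, y, spec, c_reg)

    ids = cohort["id"]
    return IndexModel(
        spec=spec,
        intercept=b0,
        coefficients=coefs,
        scaling=full_scaling,
        oof_logits=pd.Series(oof, index=pd.Index(ids, name="id"),
                             name="uaaf_index"),
        fold_of=pd.Series(folds, index=pd.Index(ids, name="id"), name="fold"),
    )
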