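"""Beta-Binomial comparison of two classifiers' accuracies.

Each model's accuracy is treated as a binomial proportion with a uniform
Beta(1, 1) prior; observing k correct predictions out of n gives the
conjugate posterior Beta(1 + k, 1 + n - k).  Superiority of model 1 over
model 0 is summarised by the posterior probability P(theta1 > theta0),
estimated from Monte-Carlo draws, together with equal-tailed 95% credible
intervals for each accuracy (exact Beta quantiles) and for the difference
theta1 - theta0 (empirical quantiles of sampled differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BetaPosterior",
    "ComparisonResult",
    "posterior_from_accuracy",
    "posterior_from_counts",
    "credible_interval",
    "compare",
]


@dataclass(frozen=True)
class BetaPosterior:
    """Beta(alpha, beta) posterior for one model's accuracy."""

    alpha: float
    beta: float
    n: int | None = None
    k: int | None = None

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class ComparisonResult:
    """Posterior summary of an accuracy comparison (model 1 vs model 0)."""

    posterior_1: BetaPosterior
    posterior_0: BetaPosterior
    p_superior: float
    ci_1: tuple[float, float]
    ci_0: tuple[float, float]
    ci_diff: tuple[float, float]
    diff_mean: float
    n_draws: int
    seed: int
    mc_se: float
    sensitivity: dict = field(default_factory=dict)


def posterior_from_counts(k: int, n: int) -> BetaPosterior:
    """Conjugate update of the Beta(1, 1) prior with k correct out of n."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return BetaPosterior(1.0 + k, 1.0 + n - k, n=n, k=k)


def posterior_from_accuracy(accuracy: float, n: int) -> BetaPosterior:
    """Posterior from a reported accuracy: k = round(accuracy * n).

    Rounding is to the nearest integer, halves away from zero, since
    published reports usually give the proportion, not the raw count.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy outside [0, 1]: {accuracy}")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = int(np.floor(accuracy * n + 0.5))
    return posterior_from_counts(min(k, n), n)


def credible_interval(posterior: BetaPosterior, level: float = 0.95):
    """Equal-tailed credible interval from exact Beta quantiles."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = stats.beta.ppf([tail, 1.0 - tail], posterior.alpha, posterior.beta)
    return float(lo), float(hi)


def _p_superior_mc(post1, post0, n_draws, rng):
    d1 = rng.beta(post1.alpha, post1.beta, n_draws)
    d0 = rng.beta(post0.alpha, post0.beta, n_draws)
    diff = d1 - d0
    return float(np.mean(d1 > d0)), diff


def compare(
    posterior_1: BetaPosterior,
    posterior_0: BetaPosterior,
    n_draws: int = 100_000,
    seed: int = 0,
    level: float = 0.95,
    sensitivity: bool = False,
) -> ComparisonResult:
    """Monte-Carlo comparison of two accuracy posteriors.

    Draws ``n_draws`` samples from each posterior; ``p_superior`` is the
    fraction of draws with theta1 > theta0 and ``ci_diff`` the equal-tailed
    empirical interval of the sampled differences.  With
    ``sensitivity=True`` (posteriors built from counts), ``p_superior`` is
    re-estimated with each count perturbed by +/-1 to show how little the
    conclusion depends on the rounding of a reported accuracy.
    """
    if n_draws < 1000:
        warnings.warn("fewer than 1000 draws gives an unstable estimate")
    rng = np.random.default_rng(seed)
    p_sup, diff = _p_superior_mc(posterior_1, posterior_0, n_draws, rng)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(diff, [tail, 1.0 - tail])
    mc_se = float(np.sqrt(max(p_sup * (1 - p_sup), 1e-12) / n_draws))

    sens = {}
    if sensitivity and posterior_1.k is not None and posterior_0.k is not None:
        for d1 in (-1, 0, 1):
            for d0 in (-1, 0, 1):
                if d1 == d0 == 0:
                    continue
                k1 = int(np.clip(posterior_1.k + d1, 0, posterior_1.n))
                k0 = int(np.clip(posterior_0.k + d0, 0, posterior_0.n))
                p, _ = _p_superior_mc(
                    posterior_from_counts(k1, posterior_1.n),
                    posterior_from_counts(k0, posterior_0.n),
                    n_draws, np.random.default_rng(seed),
                )
                sens[f"k1{d1:+d}_k0{d0:+d}"] = p

    return ComparisonResult(
        posterior_1=posterior_1,
        posterior_0=posterior_0,
        p_superior=p_sup,
        ci_1=credible_interval(posterior_1, level),
        ci_0=credible_interval(posterior_0, level),
        ci_diff=(float(lo), float(hi)),
        diff_mean=float(diff.mean()),
        n_draws=n_draws,
        seed=seed,
        mc_se=mc_se,
        sensitivity=sens,
    )
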