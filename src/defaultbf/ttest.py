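"""Default (JZS) Bayes-factor t-tests.

The alternative hypothesis places a Cauchy prior on the standardized effect
size delta = (mu1 - mu2)/sigma (or mu/sigma for one sample).  The Bayes factor
is the ratio of marginal likelihoods of the observed t statistic,

    BF10 = integral p(t | delta) pi(delta) d delta  /  p(t | 0),

where p(t | delta) is the noncentral-t density with nu degrees of freedom and
noncentrality delta * sqrt(N_eff).  One-sided tests use the folded Cauchy on
the hypothesized half-line.  With scale r -> 0 the alternative collapses onto
the null and BF10 -> 1; with two error-free equal observations the Bayes
factor is infinite (information consistency of the Cauchy prior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._quadrature import integrate_real_line
from .data import DataTable, GroupDescriptives, DataError, descriptives
from .priors import EffectSizePrior, ParameterError
from .results import BayesFactorResult, PosteriorSummary

__all__ = [
    "TTestSufficientStats", "TTestReport",
    "jzs_ttest_bf", "jzs_ttest_from_table", "posterior_delta",
    "savage_dickey_bf", "pooled_t",
]

_HYPOTHESES = ("two_sided", "group1_greater", "group2_greater")


@dataclass(frozen=True)
class TTestSufficientStats:
    """The t statistic with its sample sizes; all the test needs."""

    t: float
    n1: int
    n2: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError("t statistic must be finite")
        if self.n1 < 2 or (self.n2 is not None and self.n2 < 2):
            raise ValueError("each sample must contain at least 2 observations")
        if self.df < 1:
            raise ValueError("degrees of freedom must be at least 1")

    @property
    def df(self) -> int:
        return self.n1 - 1 if self.n2 is None else self.n1 + self.n2 - 2

    @property
    def n_eff(self) -> float:
        """Effective sample size scaling the noncentrality."""
        if self.n2 is None:
            return float(self.n1)
        return self.n1 * self.n2 / (self.n1 + self.n2)


def _posterior_kernel(t: float, df: int, sqrt_n: float,
                      prior: EffectSizePrior):
    """p(t | delta) * pi(delta), safe in the far tails.

    scipy's noncentral-t density can return NaN at astronomically large
    noncentralities probed by the tail substitution; the true value there is
    0.
    """
    def f(delta: np.ndarray) -> np.ndarray:
        vals = stats.nct.pdf(t, df, delta * sqrt_n) * prior.pdf(delta)
        return np.nan_to_num(vals, nan=0.0, posinf=0.0)

    return f


def _marginal_t(stats_: TTestSufficientStats, prior: EffectSizePrior
                ) -> tuple[float, float]:
    """(integral of p(t|delta) pi(delta), error estimate)."""
    t, df, sqrt_n = stats_.t, stats_.df, math.sqrt(stats_.n_eff)
    d_hat = t / sqrt_n

    f = _posterior_kernel(t, df, sqrt_n, prior)
    scale = max(prior.scale, 1.0 / sqrt_n)
    side = prior.side
    if side == 0:
        return integrate_real_line(f, center=d_hat, scale=scale)
    if side > 0:
        return integrate_real_line(f, center=max(d_hat, 0.0), scale=scale, lower=0.0)
    return integrate_real_line(f, center=min(d_hat, 0.0), scale=scale, upper=0.0)


def jzs_ttest_bf(stats_: TTestSufficientStats,
                 prior: EffectSizePrior | None = None) -> BayesFactorResult:
    """Bayes factor of the (possibly one-sided) JZS alternative over delta=0."""
    prior = prior or EffectSizePrior()
    if not isinstance(prior, EffectSizePrior):
        raise ParameterError("t-test requires an EffectSizePrior")
    num, num_err = _marginal_t(stats_, prior)
    null = stats.t.pdf(stats_.t, stats_.df)
    log_bf = math.log(num) - math.log(null)
    error_pct = 100.0 * num_err / num if num > 0 else None
    if error_pct is not None and error_pct < 1e-6:
        error_pct = None
    label = {0: "H1 vs H0", 1: "H+ vs H0", -1: "H- vs H0"}[prior.side]
    return BayesFactorResult(log_bf, error_pct, label)


def posterior_delta(stats_: TTestSufficientStats,
                    prior: EffectSizePrior | None = None,
                    *, ci: float = 0.95) -> PosteriorSummary:
    """Posterior median, central credible interval and density at delta = 0.

    The posterior is proportional to p(t | delta) * pi(delta); quantiles come
    from numeric inversion of the quadrature-based CDF.  One-sided priors
    yield the truncated-and-renormalized posterior on their half-line.
    """
    prior = prior or EffectSizePrior()
    t, df, sqrt_n = stats_.t, stats_.df, math.sqrt(stats_.n_eff)
    d_hat = t / sqrt_n
    scale = max(prior.scale, 1.0 / sqrt_n)

    f = _posterior_kernel(t, df, sqrt_n, prior)
    lower = 0.0 if prior.side > 0 else None
    upper = 0.0 if prior.side < 0 else None
    center = d_hat if prior.side == 0 else (max(d_hat, 0.0) if prior.side > 0
                                            else min(d_hat, 0.0))
    norm, _ = integrate_real_line(f, center=center, scale=scale,
                                  lower=lower, upper=upper)
    if not (norm > 0 and math.isfinite(norm)):
        raise RuntimeError("posterior normalization failed: "
                           f"integral = {norm!r} for t={t}, df={df}")

    lo_support = -np.inf if lower is None else lower
    hi_support = np.inf if upper is None else upper

    def cdf(x: float) -> float:
        if x <= lo_support:
            return 0.0
        val, _ = integrate_real_line(f, center=center, scale=scale,
                                     lower=lo_support if lower is not None else None,
                                     upper=x)
        return val / norm

    def quantile(p: float) -> float:
        # expand a bracket around the posterior bulk, then invert
        lo = max(d_hat - 2 * scale, lo_support + 1e-12 if lower is not None else -np.inf)
        hi = min(d_hat + 2 * scale, hi_support - 1e-12 if upper is not None else np.inf)
        if not math.isfinite(lo):
            lo = d_hat - 2 * scale
        if not math.isfinite(hi):
            hi = d_hat + 2 * scale
        while cdf(lo) > p and (lower is None or lo > lo_support + 1e-12):
            lo = lo_support + (lo - lo_support) / 4 if lower is not None else lo - 2 * scale
        while cdf(hi) < p and (upper is None or hi < hi_support - 1e-12):
            hi = hi_support - (hi_support - hi) / 4 if upper is not None else hi + 2 * scale
        return optimize.brentq(lambda x: cdf(x) - p, lo, hi, xtol=1e-8)

    alpha = (1.0 - ci) / 2.0
    lo_q, med, hi_q = quantile(alpha), quantile(0.5), quantile(1.0 - alpha)
    dens0 = float(f(np.array([0.0]))[0]) / norm
    return PosteriorSummary(med, (lo_q, hi_q), dens0)


def savage_dickey_bf(summary: PosteriorSummary,
                     prior: EffectSizePrior) -> BayesFactorResult:
    """BF01 from the posterior/prior density ratio at the null point.

    For nested hypotheses the Bayes factor equals the ratio of the posterior
    to the prior density at the test value (here delta = 0); this provides an
    independent route to the same quantity as :func:`jzs_ttest_bf`.
    """
    prior_height = prior.pdf(0.0)
    if prior_height <= 0:
        raise ParameterError("prior density at the null point is zero")
    log_bf01 = math.log(summary.density_at_zero) - math.log(prior_height)
    return BayesFactorResult(-log_bf01, None, "H1 vs H0")


def pooled_t(desc: list[GroupDescriptives]) -> TTestSufficientStats:
    """Equal-variance two-sample t statistic from group descriptives."""
    if len(desc) != 2:
        raise DataError(f"expected exactly 2 groups, found {len(desc)}")
    g1, g2 = desc
    if g1.n < 2 or g2.n < 2:
        raise DataError("each group needs at least 2 observations")
    df = g1.n + g2.n - 2
    ss = (g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2
    if ss <= 0:
        raise DataError("zero pooled variance: t statistic undefined")
    sp = math.sqrt(ss / df)
    se = sp * math.sqrt(1.0 / g1.n + 1.0 / g2.n)
    return TTestSufficientStats((g1.mean - g2.mean) / se, g1.n, g2.n)


@dataclass(frozen=True)
class TTestReport:
    """Everything the independent-samples analysis produces."""

    bf: BayesFactorResult
    posterior: PosteriorSummary
    descriptives: list[GroupDescriptives]
    stats: TTestSufficientStats
    hypothesis: str


def jzs_ttest_from_table(table: DataTable, dependent: str, group: str,
                         prior: EffectSizePrior | None = None,
                         hypothesis: str = "two_sided") -> TTestReport:
    """Two-sample JZS test straight from a long-format table.

    Group 1 is the group level that appears first in the file; delta > 0
    means its mean is larger.  ``group1_greater`` maps to the positive folded
    Cauchy, ``group2_greater`` to the negative one.
    """
    if hypothesis not in _HYPOTHESES:
        raise ParameterError(f"unknown hypothesis {hypothesis!r}")
    prior = prior or EffectSizePrior()
    desc = descriptives(table, dependent, group)
    stats_ = pooled_t(desc)
    side = {"two_sided": 0, "group1_greater": 1, "group2_greater": -1}[hypothesis]
    sided_prior = prior.folded(side)
    bf = jzs_ttest_bf(stats_, sided_prior)
    post = posterior_delta(stats_, sided_prior)
    return TTestReport(bf, post, desc, stats_, hypothesis)
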