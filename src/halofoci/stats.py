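"""Poisson modelling of per-cell focus counts and replicate statistics.

Per-cell punctum counts in exponentially growing cells are well described
by a Poisson distribution — the signature of foci forming through
independent stochastic events — except for a deficit of zero-count cells
relative to the fitted Poisson (essentially all cells carry at least one
focus).  This module provides three single-parameter estimators of the
Poisson mean:

``mle_full``
    The analytic maximum-likelihood estimate, i.e. the sample mean ("the
    average of the distribution as the only fitting parameter").
``histogram_ls``
    Least-squares fit of the Poisson pmf to the empirical relative
    frequencies over a chosen support (the histogram-fitting route used by
    interactive fitting software).
``mle_truncated``
    The zero-truncated Poisson MLE, appropriate when only counts >= 1 are
    modelled and the zero class is assessed separately.

plus an exact binomial test of the zero-class deficit, Welch's
unequal-variance t-test, and diameter/replicate summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PoissonFit",
    "SummaryStats",
    "fit_poisson",
    "zero_class_deficit",
    "welch_ttest",
    "summarize_diameters",
    "replicate_summary",
    "p_to_stars",
]


@dataclass
class PoissonFit:
    """A fitted single-parameter Poisson model for per-cell counts."""

    lambda_hat: float
    stderr: float
    method: str
    support: tuple[int, int]  # inclusive (lo, hi) used for histogram_ls
    n_cells: int
    observed_zero_fraction: float
    expected_zero_fraction: float

    def pmf(self, k: np.ndarray | int) -> np.ndarray:
        return sps.poisson.pmf(k, self.lambda_hat)


def _lambda_mle_full(counts: np.ndarray) -> float:
    return float(counts.mean())


def _lambda_histogram_ls(counts: np.ndarray, support: tuple[int, int]) -> float:
    lo, hi = support
    ks = np.arange(lo, hi + 1)
    freqs = np.array([(counts == k).mean() for k in ks])

    def sse(lam: float) -> float:
        return float(((freqs - sps.poisson.pmf(ks, lam)) ** 2).sum())

    hi_bound = max(3.0 * counts.mean(), float(hi), 1.0)
    res = optimize.minimize_scalar(sse, bounds=(1e-6, hi_bound), method="bounded")
    return float(res.x)


def _lambda_mle_truncated(counts: np.ndarray) -> float:
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError("zero-truncated fit requires at least one positive count")
    m = positive.mean()
    if m <= 1.0:
        # mean of a zero-truncated Poisson is > 1 for any lambda > 0;
        # the MLE degenerates toward 0 when the truncated mean is ~1
        return float(max(m - 1.0, 1e-8))

    def score(lam: float) -> float:
        return lam / (1.0 - math.exp(-lam)) - m

    return float(optimize.brentq(score, 1e-10, m * 2.0 + 10.0))


_ESTIMATORS = {
    "mle_full": lambda c, s: _lambda_mle_full(c),
    "histogram_ls": lambda c, s: _lambda_histogram_ls(c, s),
    "mle_truncated": lambda c, s: _lambda_mle_truncated(c),
}


def fit_poisson(
    counts,
    support: tuple[int, int] | None = None,
    method: str = "mle_full",
    n_bootstrap: int = 500,
    seed: int = 0,
) -> PoissonFit:
    """Fit a Poisson mean to per-cell counts.

    ``support`` (inclusive) is only used by ``histogram_ls``; it defaults to
    (1, 9) for ``histogram_ls``/``mle_truncated`` and (0, max(counts)) for
    ``mle_full``.  The standard error is a seeded ``n_bootstrap``-replicate
    nonparametric bootstrap.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if method not in _ESTIMATORS:
        raise ValueError(f"unknown method {method!r}")
    if support is None:
        support = (0, int(counts.max())) if method == "mle_full" else (1, 9)
    if support[1] < support[0]:
        raise ValueError("empty support")
    estimator = _ESTIMATORS[method]
    lam = estimator(counts, support)

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_bootstrap):
        sample = rng.choice(counts, size=counts.size, replace=True)
        try:
            boot.append(estimator(sample, support))
        except ValueError:
            continue
    stderr = float(np.std(boot, ddof=1)) if len(boot) > 1 else float("nan")

    return PoissonFit(
        lambda_hat=lam,
        stderr=stderr,
        method=method,
        support=(int(support[0]), int(support[1])),
        n_cells=int(counts.size),
        observed_zero_fraction=float((counts == 0).mean()),
        expected_zero_fraction=float(math.exp(-lam)),
    )


def zero_class_deficit(counts, fit: PoissonFit) -> tuple[float, float, float]:
    """Test whether zero-count cells are rarer than the fitted Poisson predicts.

    Returns ``(observed_zero_fraction, expected_zero_fraction, p)`` where
    ``p`` is the one-sided exact binomial probability of observing at most
    the observed number of zeros when each of the n cells is zero with
    probability ``exp(-lambda_hat)``.
    """
    counts = np.asarray(counts, dtype=int)
    n = counts.size
    k_zero = int((counts == 0).sum())
    expected = float(math.exp(-fit.lambda_hat))
    res = sps.binomtest(k_zero, n, expected, alternative="less")
    return k_zero / n, expected, float(res.pvalue)


def poisson_gof(counts, lambda_hat: float | None = None, min_expected: float = 5.0):
    """Chi-square goodness of fit of counts against a Poisson distribution.

    Bins 0..max(counts) are merged from the right (and left) until every
    bin's expected count is at least ``min_expected``; one degree of
    freedom is charged for the estimated mean when ``lambda_hat`` is not
    supplied.  Returns ``(chi2, df, p)``.
    """
    counts = np.asarray(counts, dtype=int)
    n = counts.size
    estimated = lambda_hat is None
    lam = counts.mean() if estimated else float(lambda_hat)
    kmax = int(counts.max())
    ks = np.arange(0, kmax + 1)
    observed = np.array([(counts == k).sum() for k in ks], dtype=float)
    expected = n * sps.poisson.pmf(ks, lam)
    # fold the open tail (> kmax) into the last bin
    expected[-1] += n * sps.poisson.sf(kmax, lam)
    # Poisson expectations are unimodal: folding both ends inward until the
    # edge bins reach min_expected leaves all bins large enough
    obs_b, exp_b = list(observed), list(expected)
    while len(exp_b) > 1 and exp_b[-1] < min_expected:
        exp_b[-2] += exp_b[-1]
        obs_b[-2] += obs_b[-1]
        exp_b.pop()
        obs_b.pop()
    while len(exp_b) > 1 and exp_b[0] < min_expected:
        exp_b[1] += exp_b[0]
        obs_b[1] += obs_b[0]
        exp_b.pop(0)
        obs_b.pop(0)
    obs_b = np.array(obs_b)
    exp_b = np.array(exp_b)
    chi2 = float(((obs_b - exp_b) ** 2 / exp_b).sum())
    df = len(exp_b) - 1 - (1 if estimated else 0)
    df = max(df, 1)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def welch_ttest(x, y) -> tuple[float, float, float]:
    """Unpaired t-test with Welch's correction.

    Returns ``(t, df, two_sided_p)`` with the Welch-Satterthwaite degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def p_to_stars(p: float) -> str:
    """Significance stars at the conventional 0.05/0.01/0.001/0.0001 levels."""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thresh:
            return stars
    return "ns"


@dataclass
class SummaryStats:
    """Summary of a sample of focus diameters (or any lengths)."""

    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    sorted_values: np.ndarray
    cdf: np.ndarray  # empirical CDF evaluated at sorted_values


def summarize_diameters(diameters) -> SummaryStats:
    """Mean, SD, 95% CI (t-based) and cumulative frequency distribution."""
    d = np.sort(np.asarray(diameters, dtype=float))
    if d.size == 0:
        raise ValueError("diameters must be non-empty")
    n = d.size
    mean = float(d.mean())
    if n == 1:
        return SummaryStats(
            n=1, mean=mean, sd=0.0, ci95=(mean, mean),
            sorted_values=d, cdf=np.array([1.0]),
        )
    sd = float(d.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return SummaryStats(
        n=n, mean=mean, sd=sd, ci95=(mean - half, mean + half),
        sorted_values=d, cdf=np.arange(1, n + 1) / n,
    )


def replicate_summary(replicates: list) -> dict:
    """Per-replicate means and the grand mean +- SD across replicates."""
    means = [float(np.mean(np.asarray(r, dtype=float))) for r in replicates]
    grand = float(np.mean(means))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return {"replicate_means": means, "grand_mean": grand, "sd": sd}
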