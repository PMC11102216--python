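"""Statistical toolkit for the group and independence analyses.

Implements the tests the cohort analysis relies on: nonparametric bootstrap
tests on group mean differences (99,999 resamples by default), Spearman
correlations with percentile-bootstrap confidence intervals, rank-based
partial correlation, Fisher's exact test of independence for 2x2
impairment tables, a Pearson chi-squared comparison of two proportions,
and step-down Bonferroni-Holm multiple-testing correction.

Bootstrap p-values use the percentile-of-zero construction with the +1
continuity correction (numerator and denominator both incremented), so the
smallest attainable p is 1 / (n_boot + 1).  Every stochastic routine takes
an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateCovariateError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)

__all__ = [
    "BootstrapResult",
    "SpearmanResult",
    "ProportionComparison",
    "bootstrap_mean_diff",
    "spearman",
    "spearman_partial",
    "fisher_exact_2x2",
    "chi2_proportions",
    "holm_correct",
    "DEFAULT_N_BOOT",
]

DEFAULT_N_BOOT = 99_999


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_lo: float
    ci_hi: float
    p: float
    n_boot: int
    tails: int
    seed: int


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_lo: float
    ci_hi: float
    p: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class ProportionComparison:
    diff: float
    ci_lo: float
    ci_hi: float
    chi2: float
    p: float


def _continuity_p(count: int, n_boot: int) -> float:
    return (count + 1) / (n_boot + 1)


def bootstrap_mean_diff(
    x,
    y,
    alternative: str = "two-sided",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap test of mean(x) - mean(y).

    Each group is resampled with replacement ``n_boot`` times; the CI is the
    2.5/97.5 percentile interval of the resampled differences.  ``alternative``
    is ``'two-sided'``, ``'greater'`` (H1: mean(x) > mean(y)) or ``'less'``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidArgumentError("each sample needs n >= 2")
    if alternative not in ("two-sided", "greater", "less"):
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    bx = rng.integers(0, x.size, size=(n_boot, x.size))
    by = rng.integers(0, y.size, size=(n_boot, y.size))
    diffs = x[bx].mean(axis=1) - y[by].mean(axis=1)
    estimate = float(np.mean(x) - np.mean(y))
    ci_lo, ci_hi = np.percentile(diffs, [2.5, 97.5])
    n_le = int(np.sum(diffs <= 0.0))
    n_ge = int(np.sum(diffs >= 0.0))
    if alternative == "two-sided":
        p = 2.0 * min(_continuity_p(n_le, n_boot), _continuity_p(n_ge, n_boot))
        tails = 2
    elif alternative == "greater":
        p = _continuity_p(n_le, n_boot)
        tails = 1
    else:
        p = _continuity_p(n_ge, n_boot)
        tails = 1
    return BootstrapResult(
        estimate=estimate,
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        p=float(min(p, 1.0)),
        n_boot=int(n_boot),
        tails=tails,
        seed=int(seed),
    )


def _rank_corr_rows(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho on (B, n) paired resamples (midranks for ties)."""
    rx = sps.rankdata(xb, axis=1)
    ry = sps.rankdata(yb, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = np.sum(rx * ry, axis=1)
    den = np.sqrt(np.sum(rx**2, axis=1) * np.sum(ry**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def spearman(
    x, y, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> SpearmanResult:
    """Spearman's rho with t-approximation p-value and percentile-bootstrap CI.

    The CI resamples (x, y) pairs with replacement; degenerate resamples
    (constant ranks) are excluded from the percentile computation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise InvalidArgumentError("paired samples with n >= 4 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input: Spearman rho undefined")
    res = sps.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    rhos = _rank_corr_rows(x[idx], y[idx])
    rhos = rhos[np.isfinite(rhos)]
    ci_lo, ci_hi = np.percentile(rhos, [2.5, 97.5])
    return SpearmanResult(
        rho=float(res.statistic),
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        p=float(res.pvalue),
        n_boot=int(n_boot),
        seed=int(seed),
    )


def spearman_partial(x, y, covariate) -> float:
    """Rank-based partial correlation of x and y controlling for one covariate.

    All three series are rank-transformed (midranks); the partial
    correlation is computed from the pairwise Pearson correlations of the
    ranks: r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.size == y.size == z.size) or x.size < 5:
        raise InvalidArgumentError("three equal-length series with n >= 5 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(z) == 0:
        raise UndefinedCorrelationError("constant input: partial rho undefined")
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    if min(1.0 - r_xz**2, 1.0 - r_yz**2) <= 1e-12:
        raise DegenerateCovariateError("covariate perfectly correlated with x or y")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2)))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test of independence for a 2x2 contingency table.

    Returns the sample odds ratio ad/bc (inf when bc = 0 and ad > 0, nan
    when both products vanish) and the two-sided probability-mass p-value
    (sum of the hypergeometric probabilities of all margin-preserving
    tables no more likely than the observed one).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InvalidArgumentError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise InvalidArgumentError("counts must be non-negative integers")
    t = t.astype(int)
    if t.sum() == 0:
        raise InvalidArgumentError("empty table")
    a, b, c, d = t.ravel()
    ad, bc = a * d, b * c
    if bc == 0:
        odds = np.inf if ad > 0 else np.nan
    else:
        odds = ad / bc
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def chi2_proportions(
    k1: int, n1: int, k2: int, n2: int, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> ProportionComparison:
    """Compare two proportions k1/n1 vs k2/n2.

    Pearson chi-squared on the 2x2 table without continuity correction
    (df = 1); the CI on the proportion difference is a percentile bootstrap
    over resampled group outcomes.
    """
    if n1 <= 0 or n2 <= 0:
        raise InvalidArgumentError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise InvalidArgumentError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    diff = p1 - p2
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = n1 + n2
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / margins
        p = float(sps.chi2.sf(chi2, df=1))
    rng = np.random.default_rng(seed)
    b1 = rng.binomial(n1, p1, size=n_boot) / n1
    b2 = rng.binomial(n2, p2, size=n_boot) / n2
    ci_lo, ci_hi = np.percentile(b1 - b2, [2.5, 97.5])
    return ProportionComparison(
        diff=float(diff), ci_lo=float(ci_lo), ci_hi=float(ci_hi), chi2=float(chi2), p=float(p)
    )


def holm_correct(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Bonferroni-Holm adjusted p-values and strict reject flags.

    Adjusted p-values are the running maximum of sorted p * (m - rank),
    clipped at 1 (monotone by construction); a hypothesis is rejected when
    its adjusted p is strictly below ``alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("pvals must be a non-empty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted < alpha
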