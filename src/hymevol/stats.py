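"""Statistical primitives shared by every contrast stage.

Mann-Whitney U (exact by enumeration for small samples, tie- and
continuity-corrected normal approximation otherwise), Pearson 2x2
chi-square with a Haldane-Anscombe odds ratio, Benjamini-Hochberg FDR,
and the coefficient of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["TestResult", "Chi2Result", "mann_whitney", "chi2_2x2", "bh_fdr", "cov"]

#: largest pooled sample size for which the exact permutation null is used
EXACT_CUTOFF = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str  # two_sided | greater | less
    method: str  # exact | normal_approx | pearson


@dataclass
class Chi2Result:
    chi2: float
    p_value: float
    odds_ratio: float
    low_expected: bool = False
    degenerate: bool = False

    def __iter__(self):
        return iter((self.chi2, self.p_value, self.odds_ratio))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a`` from midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, alternative: str = "two_sided", exact_cutoff: int | None = None) -> TestResult:
    """Mann-Whitney U test for sample ``a`` against sample ``b``.

    When the pooled sample size is at most ``exact_cutoff`` (default 12) the
    p-value is exact: all C(n_a+n_b, n_a) assignments of the pooled values to
    the two groups are enumerated and U is recomputed (midranks handle ties).
    Larger samples use the normal approximation with tie and continuity
    corrections.  ``alternative='greater'`` tests whether ``a`` is
    stochastically larger.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires nonempty samples")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    cutoff = EXACT_CUTOFF if exact_cutoff is None else exact_cutoff
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    if n_a + n_b <= cutoff:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        offset = n_a * (n_a + 1) / 2.0
        us = np.array(
            [ranks[list(idx)].sum() - offset for idx in combinations(range(n_a + n_b), n_a)]
        )
        eps = 1e-9
        if alternative == "greater":
            p = float(np.mean(us >= u_obs - eps))
        elif alternative == "less":
            p = float(np.mean(us <= u_obs + eps))
        else:
            mu = n_a * n_b / 2.0
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - eps))
        return TestResult(u_obs, min(p, 1.0), alternative, "exact")
    scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = sps.mannwhitneyu(a, b, alternative=scipy_alt, method="asymptotic", use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, "normal_approx")


def chi2_2x2(table, yates: bool = False) -> Chi2Result:
    """Pearson chi-square (df=1) on a 2x2 table with an odds ratio.

    No Yates continuity correction by default.  The odds ratio ad/bc gets the
    Haldane-Anscombe +0.5 added to every cell iff any cell is zero.  A table
    with a zero row or column total is degenerate: chi2=0, p=1.  The
    ``low_expected`` flag marks any expected count below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("chi2_2x2 needs a nonnegative 2x2 table")
    if t.sum() < 1:
        raise ValueError("chi2_2x2 needs a grand total >= 1")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return Chi2Result(0.0, 1.0, 1.0, low_expected=True, degenerate=True)
    expected = np.outer(rows, cols) / t.sum()
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    h = t + 0.5 if np.any(t == 0) else t
    odds = float(h[0, 0] * h[1, 1] / (h[0, 1] * h[1, 0]))
    return Chi2Result(chi2, p, odds, low_expected=bool(np.any(expected < 5)))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cov(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over the mean.

    Undefined for fewer than two values or a zero mean; returns NaN with a
    logged reason in those cases.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        logger.info("cov undefined: fewer than 2 values")
        return float("nan")
    mean = v.mean()
    if mean == 0:
        logger.info("cov undefined: zero mean")
        return float("nan")
    return float(v.std(ddof=1) / mean)
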