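"""dN/dS-based clade contrasts and normalized evolutionary rates.

The sampling unit throughout is the per-branch free-ratio-style omega
(dN/dS) of a family: per-family two-sided location tests between clades,
per-family coefficients of variation (CoV) with a global one-tailed
dispersion contrast, a decile-intersection screen for families that are
highly variable in one clade and stable in the other, and the normalized
evolutionary rate (mean ratio of a family's branch substitution rates to
the genome-wide branch rates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contrast import ContrastReport, _check_disjoint, _finish_mw_table
from .stats import TestResult, cov, mann_whitney
from .tree import CladeResolution

logger = logging.getLogger(__name__)

__all__ = ["og_dnds_contrast", "cov_contrast", "CovContrast", "normalized_rate"]


def _clade_values(rates: pd.DataFrame, clade: CladeResolution) -> pd.core.groupby.SeriesGroupBy:
    sub = rates[rates["branch_id"].isin(clade.branch_ids)]
    return sub.groupby("og_id")["omega"]


def og_dnds_contrast(rates: pd.DataFrame, clade_a: CladeResolution, clade_b: CladeResolution,
                     alpha_fdr: float = 0.05, min_branches: int = 2) -> ContrastReport:
    """Two-sided per-family Mann-Whitney contrast of branch omega values.

    ``rates`` is a long table (og_id, branch_id, omega).  Families with
    fewer than ``min_branches`` omega values in either clade are skipped.
    """
    _check_disjoint(clade_a, clade_b, "branches")
    grp_a = dict(iter(_clade_values(rates, clade_a)))
    grp_b = dict(iter(_clade_values(rates, clade_b)))
    skipped: dict[str, str] = {}
    rows = []
    for og in sorted(set(grp_a) | set(grp_b)):
        va = grp_a.get(og)
        vb = grp_b.get(og)
        if va is None or vb is None or len(va) < min_branches or len(vb) < min_branches:
            skipped[og] = "below minimum branch support"
            continue
        res = mann_whitney(va.values, vb.values, "two_sided")
        rows.append((og, len(va), len(vb), res.statistic, res.p_value))
    table = pd.DataFrame(rows, columns=["og_id", "n_a", "n_b", "statistic", "p"]).set_index("og_id")
    _finish_mw_table(table, clade_a.name, clade_b.name, "two_sided", alpha_fdr)
    if skipped:
        logger.info("og_dnds_contrast: skipped %d families", len(skipped))
    return ContrastReport("og_dnds_contrast", clade_a.name, clade_b.name, table,
                          alpha_fdr, skipped)


@dataclass
class CovContrast:
    """Dispersion contrast of per-family omega CoV between two clades."""

    global_test: TestResult
    fraction_a_greater: float
    fraction_b_greater: float
    fraction_tied: float
    intersection: list[str]
    cov_table: pd.DataFrame  # per family: cov_a, cov_b


def cov_contrast(rates: pd.DataFrame, clade_a: CladeResolution, clade_b: CladeResolution,
                 top_frac: float = 0.10, bottom_frac: float = 0.10,
                 min_branches: int = 2) -> CovContrast:
    """Compare omega dispersion (CoV) between clades, family by family.

    Per family the CoV of branch omega values is computed in each clade;
    the global test is a one-tailed Mann-Whitney across families (is the
    CoV distribution of clade A shifted above clade B?).  The intersection
    lists families in the top ``top_frac`` of clade-A CoV *and* the bottom
    ``bottom_frac`` of clade-B CoV (empirical quantiles, boundary
    inclusive).
    """
    _check_disjoint(clade_a, clade_b, "branches")
    grp_a = dict(iter(_clade_values(rates, clade_a)))
    grp_b = dict(iter(_clade_values(rates, clade_b)))
    rows = []
    for og in sorted(set(grp_a) & set(grp_b)):
        va, vb = grp_a[og], grp_b[og]
        if len(va) < min_branches or len(vb) < min_branches:
            continue
        ca, cb = cov(va.values), cov(vb.values)
        if np.isnan(ca) or np.isnan(cb):
            continue
        rows.append((og, ca, cb))
    if not rows:
        raise ValueError("no family passes the support filter")
    tab = pd.DataFrame(rows, columns=["og_id", "cov_a", "cov_b"]).set_index("og_id")
    gt = mann_whitney(tab["cov_a"].values, tab["cov_b"].values, "greater")
    fa = float((tab["cov_a"] > tab["cov_b"]).mean())
    fb = float((tab["cov_a"] < tab["cov_b"]).mean())
    thr_a = np.quantile(tab["cov_a"].values, 1.0 - top_frac)
    thr_b = np.quantile(tab["cov_b"].values, bottom_frac)
    inter = tab.index[(tab["cov_a"] >= thr_a) & (tab["cov_b"] <= thr_b)]
    return CovContrast(gt, fa, fb, 1.0 - fa - fb, sorted(inter), tab)


def normalized_rate(og_rates, genome_rates) -> float:
    """Mean over branches of (family rate / genome-wide rate).

    Both inputs are aligned per-branch vectors (or Series sharing a branch
    index).  Branches with zero genome-wide rate are excluded and logged.
    """
    if isinstance(og_rates, pd.Series) and isinstance(genome_rates, pd.Series):
        genome_rates = genome_rates.reindex(og_rates.index)
    og = np.asarray(og_rates, dtype=float)
    gen = np.asarray(genome_rates, dtype=float)
    if og.shape != gen.shape:
        raise ValueError("rate vectors must align on the same branch set")
    usable = gen > 0
    if not usable.any():
        raise ValueError("no branch with positive genome-wide rate")
    if (~usable).any():
        logger.info("normalized_rate: excluded %d zero-rate branches", int((~usable).sum()))
    return float(np.mean(og[usable] / gen[usable]))
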