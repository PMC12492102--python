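"""Family-level contrasts between two named clades.

Implements the comparisons made between the Parasitoida and Aculeata
clades: enrichment of rapid turnover events (per-family 2x2 chi-square
with odds ratio), gain/loss-rate contrast and family-size contrast
(one-tailed Mann-Whitney scans, BH-adjusted over the tested families),
and the presence/absence classification rules (missing vs novel core
families, differential loss).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr, chi2_2x2, mann_whitney
from .tree import CladeResolution

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastReport",
    "rapid_enrichment",
    "rate_contrast",
    "size_contrast",
    "presence_classes",
    "differential_loss",
]


@dataclass
class ContrastReport:
    """Result of one per-family contrast scan.

    ``table`` has one row per tested unit with at least the columns
    (n_a, n_b, statistic, p, p_adj, direction, decision); the BH adjustment
    is over exactly the rows present, so every decision is reproducible from
    the table itself.
    """

    name: str
    clade_a: str
    clade_b: str
    table: pd.DataFrame
    alpha_fdr: float = 0.05
    skipped: dict[str, str] = field(default_factory=dict, repr=False)

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["decision"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["decision"].sum())


def _check_disjoint(a: CladeResolution, b: CladeResolution, what: str):
    if a.branch_ids & b.branch_ids:
        raise ValueError(f"clades {a.name} and {b.name} share {what}")


def rapid_enrichment(events: pd.DataFrame, clade_a: CladeResolution,
                     clade_b: CladeResolution, alpha_fdr: float = 0.05) -> ContrastReport:
    """Per-family enrichment of rapid events in clade A over clade B.

    For each family, a 2x2 table (rows = clades, columns = rapid vs
    non-rapid branches) is tested by Pearson chi-square; families with no
    rapid event in either clade are excluded before the BH adjustment.
    A family is enriched in A iff adjusted p < alpha and odds ratio > 1.
    """
    _check_disjoint(clade_a, clade_b, "branches")
    if not clade_a.branch_ids or not clade_b.branch_ids:
        raise ValueError("each clade needs at least one branch")
    in_a = events["branch_id"].isin(clade_a.branch_ids)
    in_b = events["branch_id"].isin(clade_b.branch_ids)
    n_a = len(clade_a.branch_ids)
    n_b = len(clade_b.branch_ids)
    rapid_a = events.loc[in_a].groupby("og_id")["rapid"].sum()
    rapid_b = events.loc[in_b].groupby("og_id")["rapid"].sum()
    ogs = rapid_a.index.union(rapid_b.index)
    rapid_a = rapid_a.reindex(ogs, fill_value=0).astype(int)
    rapid_b = rapid_b.reindex(ogs, fill_value=0).astype(int)
    tested = ogs[(rapid_a + rapid_b) > 0]
    skipped = {og: "no rapid events in either clade" for og in ogs.difference(tested)}
    rows = []
    for og in tested:
        ra, rb = int(rapid_a[og]), int(rapid_b[og])
        res = chi2_2x2([[ra, n_a - ra], [rb, n_b - rb]])
        rows.append((og, ra, rb, res.chi2, res.p_value, res.odds_ratio))
    table = pd.DataFrame(
        rows, columns=["og_id", "n_a", "n_b", "statistic", "p", "odds_ratio"]
    ).set_index("og_id")
    if len(table):
        table["p_adj"] = bh_fdr(table["p"].values)
        table["direction"] = np.where(table["odds_ratio"] > 1, clade_a.name,
                                      np.where(table["odds_ratio"] < 1, clade_b.name, "tie"))
        table["decision"] = (table["p_adj"] < alpha_fdr) & (table["odds_ratio"] > 1)
    else:
        table["p_adj"] = []
        table["direction"] = []
        table["decision"] = []
    return ContrastReport("rapid_enrichment", clade_a.name, clade_b.name, table,
                          alpha_fdr, skipped)


def rate_contrast(results, clade_a: CladeResolution, clade_b: CladeResolution,
                  alternative: str = "greater", alpha_fdr: float = 0.05) -> ContrastReport:
    """Per-family gain/loss-rate contrast between two clades.

    For each family the per-branch rates |delta|/t over each clade's
    branches (zero-length branches skipped) are compared with a one-tailed
    Mann-Whitney U test (is clade A faster?), BH-adjusted over all tested
    families.  ``results`` is a :class:`~hymevol.dynamics.TurnoverResults`.
    """
    _check_disjoint(clade_a, clade_b, "branches")
    rates_a = results.branch_rates(sorted(clade_a.branch_ids))
    rates_b = results.branch_rates(sorted(clade_b.branch_ids))
    skipped: dict[str, str] = {}
    rows = []
    for og in results.deltas.index:
        va = rates_a.loc[og].values
        vb = rates_b.loc[og].values
        if len(va) < 2 or len(vb) < 2:
            skipped[og] = "fewer than 2 usable branches in a clade"
            continue
        res = mann_whitney(va, vb, alternative)
        rows.append((og, len(va), len(vb), res.statistic, res.p_value))
    table = pd.DataFrame(rows, columns=["og_id", "n_a", "n_b", "statistic", "p"]).set_index("og_id")
    _finish_mw_table(table, clade_a.name, clade_b.name, alternative, alpha_fdr)
    if skipped:
        logger.info("rate_contrast: skipped %d families", len(skipped))
    return ContrastReport("rate_contrast", clade_a.name, clade_b.name, table, alpha_fdr, skipped)


def _finish_mw_table(table: pd.DataFrame, name_a: str, name_b: str,
                     alternative: str, alpha_fdr: float):
    if len(table) == 0:
        table["p_adj"] = []
        table["direction"] = []
        table["decision"] = []
        return
    table["p_adj"] = bh_fdr(table["p"].values)
    mu = table["n_a"] * table["n_b"] / 2.0
    table["direction"] = np.where(table["statistic"] > mu, name_a,
                                  np.where(table["statistic"] < mu, name_b, "tie"))
    table["decision"] = table["p_adj"] < alpha_fdr
    if alternative == "greater":
        table["decision"] &= table["statistic"] > mu
    elif alternative == "less":
        table["decision"] &= table["statistic"] < mu


def size_contrast(counts: pd.DataFrame, species_a, species_b,
                  alternative: str = "greater", alpha_fdr: float = 0.05,
                  name_a: str = "A", name_b: str = "B") -> ContrastReport:
    """Per-family size contrast: per-species counts, one-tailed Mann-Whitney."""
    species_a = sorted(species_a)
    species_b = sorted(species_b)
    both = set(species_a) & set(species_b)
    if both:
        raise ValueError(f"species in both groups: {sorted(both)}")
    if len(species_a) < 2 or len(species_b) < 2:
        raise ValueError("each group needs at least 2 species")
    unused = set(counts.columns) - set(species_a) - set(species_b)
    if unused:
        logger.warning("size_contrast: %d species in neither group", len(unused))
    rows = []
    for og in counts.index:
        va = counts.loc[og, species_a].values.astype(float)
        vb = counts.loc[og, species_b].values.astype(float)
        res = mann_whitney(va, vb, alternative)
        rows.append((og, len(va), len(vb), res.statistic, res.p_value))
    table = pd.DataFrame(rows, columns=["og_id", "n_a", "n_b", "statistic", "p"]).set_index("og_id")
    _finish_mw_table(table, name_a, name_b, alternative, alpha_fdr)
    return ContrastReport("size_contrast", name_a, name_b, table, alpha_fdr)


def presence_classes(counts: pd.DataFrame, test_species, outgroup_species,
                     presence_frac: float = 0.70, max_absent_side_frac: float = 0.0
                     ) -> tuple[list[str], list[str]]:
    """Classify families as missing or novel-core for a test group.

    A species "has" a family iff its count is >= 1.  *Missing* families are
    present in strictly more than ``presence_frac`` of outgroup species and
    present in at most ``max_absent_side_frac`` (default: none) of test
    species; *novel core* families are the mirror image (retained in over
    ``presence_frac`` of the test group, absent from the outgroup).
    """
    test_species = sorted(test_species)
    outgroup_species = sorted(outgroup_species)
    if not test_species or not outgroup_species:
        raise ValueError("both groups must be nonempty")
    if set(test_species) & set(outgroup_species):
        raise ValueError("test and outgroup species overlap")
    pres = counts >= 1
    f_test = pres[test_species].mean(axis=1)
    f_out = pres[outgroup_species].mean(axis=1)
    missing = counts.index[(f_out > presence_frac) & (f_test <= max_absent_side_frac)]
    novel = counts.index[(f_test > presence_frac) & (f_out <= max_absent_side_frac)]
    return list(missing), list(novel)


def differential_loss(counts: pd.DataFrame, clade_species, other_species,
                      frac_a: float = 0.20, frac_other: float = 0.02) -> list[str]:
    """Families lost in > ``frac_a`` of clade species but <= ``frac_other``
    elsewhere ("lost" meaning count 0).  Boundary semantics are strict on
    the clade side and inclusive on the other side."""
    clade_species = sorted(clade_species)
    other_species = sorted(other_species)
    if not clade_species or not other_species:
        raise ValueError("both groups must be nonempty")
    if set(clade_species) & set(other_species):
        raise ValueError("groups overlap")
    lost = counts == 0
    f_a = lost[clade_species].mean(axis=1)
    f_o = lost[other_species].mean(axis=1)
    return list(counts.index[(f_a > frac_a) & (f_o <= frac_other)])
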