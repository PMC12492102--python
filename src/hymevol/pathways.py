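"""Ancestral metabolic-pathway reconstruction and coverage contrasts.

An *ancestral pathway* is the subset of a reference pathway's EC numbers
inferred present in the common ancestor from outgroup annotations (the
combine of the outgroup species' EC sets intersected with the pathway's
ECs).  *Pathway coverage* (PC) of a species is the fraction of the
ancestral ECs annotated in it.  Contrasts compare PC and its coefficient
of variation between two clades.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrast import ContrastReport
from .stats import TestResult, bh_fdr, cov, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "validate_pathway_table",
    "AncestralPathwaySet",
    "build_ancestral",
    "coverage",
    "coverage_matrix",
    "pc_contrast",
    "pc_cov_contrast",
]

EC_PATTERN = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def validate_pathway_table(db: pd.DataFrame) -> pd.DataFrame:
    """Check a pathway table (pathway_id, superpathway_id, name,
    has_reference, ecs) for EC-pattern violations and empty EC sets."""
    required = {"pathway_id", "superpathway_id", "has_reference", "ecs"}
    missing = required - set(db.columns)
    if missing:
        raise ValueError(f"pathway table missing columns: {sorted(missing)}")
    for _, row in db.iterrows():
        if not row["ecs"]:
            raise ValueError(f"pathway {row['pathway_id']} has an empty EC set")
        for ec in row["ecs"]:
            if not EC_PATTERN.match(ec):
                raise ValueError(f"invalid EC number {ec!r} in pathway {row['pathway_id']}")
    return db


@dataclass
class AncestralPathwaySet:
    """Pathway id -> retained EC set, with superpathway labels and provenance."""

    retained: dict[str, frozenset[str]]
    superpathway: dict[str, str]
    mode: str
    outgroup_species: tuple[str, ...]
    dropped: dict[str, str] = field(default_factory=dict, repr=False)

    def __len__(self):
        return len(self.retained)


def _combine(ec_sets: list[set[str]], mode: str) -> set[str]:
    if mode == "union":
        out: set[str] = set()
        for s in ec_sets:
            out |= s
        return out
    if mode == "intersection":
        out = set(ec_sets[0])
        for s in ec_sets[1:]:
            out &= s
        return out
    if mode == "majority":
        counts: dict[str, int] = {}
        for s in ec_sets:
            for ec in s:
                counts[ec] = counts.get(ec, 0) + 1
        half = len(ec_sets) / 2.0
        return {ec for ec, c in counts.items() if c > half}
    raise ValueError(f"unknown combine mode {mode!r}")


def build_ancestral(db: pd.DataFrame, outgroup_ecs: dict[str, set[str]],
                    mode: str = "union", min_ecs: int = 5,
                    require_reference: bool = True) -> AncestralPathwaySet:
    """Reconstruct ancestral pathways from outgroup EC annotations.

    Per pathway the outgroup EC sets are combined (union by default;
    intersection and majority(>50%) available) and intersected with the
    pathway's ECs; a pathway is kept iff it retains at least ``min_ecs``
    enzymes and, when ``require_reference``, has a reference-species
    pathway.
    """
    validate_pathway_table(db)
    if not outgroup_ecs:
        raise ValueError("outgroup EC annotations are empty")
    ancestor = _combine([set(v) for _, v in sorted(outgroup_ecs.items())], mode)
    retained: dict[str, frozenset[str]] = {}
    superpathway: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for _, row in db.iterrows():
        pid = row["pathway_id"]
        if require_reference and not row["has_reference"]:
            dropped[pid] = "no reference-species pathway"
            continue
        keep = frozenset(ancestor & set(row["ecs"]))
        if len(keep) < min_ecs:
            dropped[pid] = f"only {len(keep)} ancestral ECs (< {min_ecs})"
            continue
        retained[pid] = keep
        superpathway[pid] = row["superpathway_id"]
    if dropped:
        logger.info("build_ancestral: dropped %d pathways", len(dropped))
    return AncestralPathwaySet(retained, superpathway, mode,
                               tuple(sorted(outgroup_ecs)), dropped)


def _match_count(species_ecs: set[str], retained: frozenset[str], match: str) -> int:
    if match == "literal":
        return len(species_ecs & retained)
    if match != "wildcard":
        raise ValueError(f"unknown EC match mode {match!r}")
    hit = set()
    wild = [ec.split(".") for ec in species_ecs if "-" in ec]
    exact = species_ecs & retained
    for r in retained:
        if r in exact:
            hit.add(r)
            continue
        rp = r.split(".")
        for wp in wild:
            if all(w == "-" or w == p for w, p in zip(wp, rp)):
                hit.add(r)
                break
    return len(hit)


def coverage(species_ecs: set[str], ancestral: AncestralPathwaySet,
             match: str = "literal") -> pd.Series:
    """Pathway coverage of one species: |annotated ∩ retained| / |retained|."""
    if not ancestral.retained:
        raise ValueError("ancestral pathway set is empty")
    return pd.Series(
        {
            pid: _match_count(species_ecs, keep, match) / len(keep)
            for pid, keep in ancestral.retained.items()
        }
    ).sort_index()


def coverage_matrix(profiles: dict[str, set[str]], ancestral: AncestralPathwaySet,
                    match: str = "literal") -> pd.DataFrame:
    """PC matrix, pathways x species."""
    cols = {sp: coverage(ecs, ancestral, match) for sp, ecs in sorted(profiles.items())}
    out = pd.DataFrame(cols)
    out.index.name = "pathway_id"
    return out


def pc_contrast(cov_matrix: pd.DataFrame, species_a, species_b,
                alternative: str = "less", alpha_fdr: float = 0.05,
                name_a: str = "A", name_b: str = "B",
                joint_bh: bool = False) -> tuple[TestResult, ContrastReport]:
    """Global and per-pathway coverage contrast between two species groups.

    The global test pools every (pathway, species) PC value per group into
    one one-tailed Mann-Whitney test (default: is group A lower?).  Per
    pathway, both one-tailed tests on the species PC vectors are reported,
    each BH-adjusted over the tested pathways (``joint_bh`` adjusts both
    directions together instead).
    """
    species_a = sorted(set(species_a) & set(cov_matrix.columns))
    species_b = sorted(set(species_b) & set(cov_matrix.columns))
    if len(species_a) < 2 or len(species_b) < 2:
        raise ValueError("each clade needs >= 2 species with coverage values")
    pooled_a = cov_matrix[species_a].values.ravel()
    pooled_b = cov_matrix[species_b].values.ravel()
    global_test = mann_whitney(pooled_a, pooled_b, alternative)
    rows = []
    skipped: dict[str, str] = {}
    for pid in cov_matrix.index:
        va = cov_matrix.loc[pid, species_a].values
        vb = cov_matrix.loc[pid, species_b].values
        if len(va) < 2 or len(vb) < 2:
            skipped[pid] = "fewer than 2 species in a clade"
            continue
        lo = mann_whitney(va, vb, "less")
        hi = mann_whitney(va, vb, "greater")
        rows.append((pid, len(va), len(vb), lo.statistic, lo.p_value, hi.p_value))
    table = pd.DataFrame(
        rows, columns=["pathway_id", "n_a", "n_b", "statistic", "p_less", "p_greater"]
    ).set_index("pathway_id")
    if len(table):
        if joint_bh:
            adj = bh_fdr(np.concatenate([table["p_less"].values, table["p_greater"].values]))
            table["p_adj_less"] = adj[: len(table)]
            table["p_adj_greater"] = adj[len(table):]
        else:
            table["p_adj_less"] = bh_fdr(table["p_less"].values)
            table["p_adj_greater"] = bh_fdr(table["p_greater"].values)
        table["lower_in_a"] = table["p_adj_less"] < alpha_fdr
        table["higher_in_a"] = table["p_adj_greater"] < alpha_fdr
        side = "p_adj_less" if alternative == "less" else "p_adj_greater"
        table["p"] = table["p_less" if alternative == "less" else "p_greater"]
        table["p_adj"] = table[side]
        table["direction"] = np.where(table["lower_in_a"], name_b,
                                      np.where(table["higher_in_a"], name_a, "tie"))
        table["decision"] = table["lower_in_a"] if alternative == "less" else table["higher_in_a"]
    report = ContrastReport("pc_contrast", name_a, name_b, table, alpha_fdr, skipped)
    return global_test, report


def pc_cov_contrast(cov_matrix: pd.DataFrame, ancestral: AncestralPathwaySet,
                    species_a, species_b, alpha_fdr: float = 0.05,
                    min_pathways: int = 2, name_a: str = "A", name_b: str = "B"
                    ) -> ContrastReport:
    """Per-superpathway contrast of PC variability (CoV) between clades.

    For each pathway and clade, the CoV of PC across the clade's species is
    computed; per superpathway, the pathways' clade-A CoV values are tested
    against the clade-B values (one-tailed Mann-Whitney, A greater), with
    BH adjustment across superpathways.
    """
    species_a = sorted(set(species_a) & set(cov_matrix.columns))
    species_b = sorted(set(species_b) & set(cov_matrix.columns))
    cov_a = {}
    cov_b = {}
    for pid in cov_matrix.index:
        ca = cov(cov_matrix.loc[pid, species_a].values)
        cb = cov(cov_matrix.loc[pid, species_b].values)
        if not (np.isnan(ca) or np.isnan(cb)):
            cov_a[pid], cov_b[pid] = ca, cb
    groups: dict[str, list[str]] = {}
    for pid in cov_a:
        groups.setdefault(ancestral.superpathway[pid], []).append(pid)
    rows = []
    skipped: dict[str, str] = {}
    for sp_id in sorted(groups):
        pids = groups[sp_id]
        if len(pids) < min_pathways:
            skipped[sp_id] = f"only {len(pids)} pathways (< {min_pathways})"
            continue
        va = np.array([cov_a[p] for p in pids])
        vb = np.array([cov_b[p] for p in pids])
        res = mann_whitney(va, vb, "greater")
        rows.append((sp_id, len(pids), len(pids), res.statistic, res.p_value))
    table = pd.DataFrame(
        rows, columns=["superpathway_id", "n_a", "n_b", "statistic", "p"]
    ).set_index("superpathway_id")
    if len(table):
        table["p_adj"] = bh_fdr(table["p"].values)
        mu = table["n_a"] * table["n_b"] / 2.0
        table["direction"] = np.where(table["statistic"] > mu, name_a,
                                      np.where(table["statistic"] < mu, name_b, "tie"))
        table["decision"] = (table["p_adj"] < alpha_fdr) & (table["statistic"] > mu)
    else:
        table["p_adj"] = []
        table["direction"] = []
        table["decision"] = []
    if skipped:
        logger.info("pc_cov_contrast: skipped superpathways: %s", sorted(skipped))
    return ContrastReport("pc_cov_contrast", name_a, name_b, table, alpha_fdr, skipped)
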