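"""Synthetic data with the statistical structure the analyses assume.

Three generators, all seeded and deterministic:

* integer gene-family counts evolving along the tree by a linear
  birth-death process per gene copy (Gillespie stepping), with optional
  clade-specific rate multipliers;
* per-(family, branch) dN/dS values: a baseline omega times a clade factor
  times mean-one lognormal noise of chosen coefficient of variation;
* per-species enzyme (EC) repertoires derived from full ancestral pathway
  EC sets by clade-specific independent enzyme loss.

A small random ultrametric demo tree (outgroup + two focal sister clades)
and a synthetic pathway table are also provided so the whole pipeline can
run with no external inputs.  Randomness is split into counter-based
substreams per family / species (``SeedSequence(seed, spawn_key=...)``) so
results do not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import CladeResolution, CladeSpec, TimeTree, parse_newick, resolve_clade

__all__ = [
    "SimConfig",
    "simulate_counts",
    "simulate_branch_rates",
    "simulate_ec_profiles",
    "simulate_tree",
    "balanced_study_tree",
    "simulate_pathways",
]

# substream domains, so the three generators never share a stream
_STREAM_COUNTS = 1
_STREAM_RATES = 2
_STREAM_EC = 3
_STREAM_TREE = 4


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 2,000 gene families on a 32-leaf, 500-My-total-length tree, with
    per-copy gain and loss rates of 0.005/My and geometric(0.5) root counts
    (support >= 1, mean 2).
    """

    seed: int = 0
    n_families: int = 2000
    root_count_law: tuple[str, float] = ("geometric", 0.5)
    gain_rate_per_copy_my: float = 0.005
    loss_rate_per_copy_my: float = 0.005
    clade_multipliers: dict[str, float] = field(default_factory=dict)
    omega_base: float = 0.2
    omega_clade_shift: dict[str, float] = field(default_factory=dict)
    omega_noise_cv: float = 0.3
    ec_loss_prob: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.gain_rate_per_copy_my < 0 or self.loss_rate_per_copy_my < 0:
            raise ValueError("rates must be nonnegative")
        if self.omega_base <= 0 or self.omega_noise_cv < 0:
            raise ValueError("omega_base must be > 0 and omega_noise_cv >= 0")
        for name, m in self.clade_multipliers.items():
            if not m > 0:
                raise ValueError(f"clade multiplier for {name} must be > 0")
        for name, p in self.ec_loss_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"ec_loss_prob for {name} must be in [0, 1]")
        law, par = self.root_count_law
        if law not in ("geometric", "fixed"):
            raise ValueError(f"unknown root_count_law {law!r}")


def _branch_factor(tree: TimeTree, clades: dict[str, CladeResolution] | None,
                   per_clade: dict[str, float]) -> np.ndarray:
    """Multiplicative factor per branch (post-order, excluding root)."""
    factor = np.ones(tree.n_nodes - 1)
    if not per_clade:
        return factor
    if clades is None:
        raise ValueError("clade-specific parameters given but no clades resolved")
    ids = tree.branch_ids
    pos = {b: i for i, b in enumerate(ids)}
    for name, m in per_clade.items():
        if name not in clades:
            raise KeyError(f"unknown clade in config: {name}")
        for b in clades[name].branch_ids:
            factor[pos[b]] *= m
    return factor


def _root_count(cfg: SimConfig, rng: np.random.Generator) -> int:
    law, par = cfg.root_count_law
    if law == "fixed":
        return int(par)
    return int(rng.geometric(par))  # support {1, 2, ...}


def _gillespie_branch(n0: int, t_total: float, gain: float, loss: float,
                      rng: np.random.Generator) -> int:
    """Copy number after time ``t_total`` under per-copy gain/loss rates."""
    n = n0
    t = 0.0
    total = gain + loss
    while n > 0 and total > 0:
        rate = n * total
        t += rng.exponential(1.0 / rate)
        if t > t_total:
            break
        if rng.random() < gain / total:
            n += 1
        else:
            n -= 1
    return n


def simulate_counts(tree: TimeTree, cfg: SimConfig,
                    clades: dict[str, CladeResolution] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate family counts and return (leaf count matrix, true event table).

    Counts evolve from a root draw by a linear birth-death process per copy
    along every branch; size zero is absorbing (a gained gene needs a
    template copy), so a family lost on a branch stays lost below it.  The
    true event table records the child-minus-parent count per branch.
    """
    factor = _branch_factor(tree, clades, cfg.clade_multipliers)
    leaves = tree.leaves
    branch_ids = tree.branch_ids
    n_b = len(branch_ids)
    branch_pos = {tree.node_of(b): i for i, b in enumerate(branch_ids)}
    # preorder traversal order (parents before children)
    preorder = list(range(tree.n_nodes - 1, -1, -1))
    counts = np.zeros((cfg.n_families, len(leaves)), dtype=int)
    deltas = np.zeros((cfg.n_families, n_b), dtype=int)
    leaf_pos = {nm: i for i, nm in enumerate(leaves)}
    g, l = cfg.gain_rate_per_copy_my, cfg.loss_rate_per_copy_my
    for f in range(cfg.n_families):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_COUNTS, f)))
        state = np.zeros(tree.n_nodes, dtype=int)
        state[tree.root] = _root_count(cfg, rng)
        for v in preorder:
            for c in tree.children[v]:
                i = branch_pos[c]
                m = factor[i]
                state[c] = _gillespie_branch(state[v], tree.length[c], g * m, l * m, rng)
                deltas[f, i] = state[c] - state[v]
        for v in range(tree.n_nodes):
            if tree.is_leaf[v]:
                counts[f, leaf_pos[tree.leaf_name[v]]] = state[v]
    og_ids = [f"OG{f:07d}" for f in range(cfg.n_families)]
    count_df = pd.DataFrame(counts, index=pd.Index(og_ids, name="Orthogroup"), columns=leaves)
    delta_df = pd.DataFrame(deltas, index=pd.Index(og_ids, name="og_id"), columns=branch_ids)
    return count_df, delta_df


def simulate_branch_rates(tree: TimeTree, n_ogs: int, cfg: SimConfig,
                          clades: dict[str, CladeResolution] | None = None) -> pd.DataFrame:
    """Simulate per-(OG, branch) dN/dS: base x clade factor x lognormal noise.

    The lognormal noise has mean one and coefficient of variation
    ``cfg.omega_noise_cv`` (``sigma^2 = ln(1 + cv^2)``), so omega stays
    strictly positive and clade shifts act multiplicatively on its location.
    Returns a long table (og_id, branch_id, omega).
    """
    if n_ogs < 1:
        raise ValueError("n_ogs must be >= 1")
    factor = _branch_factor(tree, clades, cfg.omega_clade_shift)
    branch_ids = tree.branch_ids
    n_b = len(branch_ids)
    cv = cfg.omega_noise_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    for f in range(n_ogs):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_RATES, f)))
        if sigma > 0:
            noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n_b)
        else:
            noise = np.ones(n_b)
        rows.append(cfg.omega_base * factor * noise)
    omega = np.asarray(rows)
    og_ids = [f"OG{f:07d}" for f in range(n_ogs)]
    long = pd.DataFrame(
        {
            "og_id": np.repeat(og_ids, n_b),
            "branch_id": np.tile(branch_ids, n_ogs),
            "omega": omega.ravel(),
        }
    )
    return long


def simulate_ec_profiles(pathways: pd.DataFrame, tree: TimeTree, cfg: SimConfig,
                         clades: dict[str, CladeResolution], outgroup: str = "Outgroup"
                         ) -> dict[str, set[str]]:
    """Per-species EC sets: outgroup keeps all pathway ECs, others lose some.

    Every species in the clade named ``outgroup`` carries the full union of
    pathway EC sets.  Any other species independently drops each EC with its
    clade's ``ec_loss_prob`` (0 for species in no configured clade).
    """
    if pathways.empty:
        raise ValueError("pathway table is empty")
    for name in cfg.ec_loss_prob:
        if name not in clades:
            raise KeyError(f"unknown clade in ec_loss_prob: {name}")
    if outgroup not in clades:
        raise KeyError(f"outgroup clade {outgroup!r} not resolved")
    full: set[str] = set()
    for ecs in pathways["ecs"]:
        full |= set(ecs)
    full_sorted = sorted(full)
    species_clade: dict[str, str | None] = {}
    for sp in tree.leaves:
        species_clade[sp] = None
        for name, res in clades.items():
            if sp in res.species:
                species_clade[sp] = name
                break
    profiles: dict[str, set[str]] = {}
    for s, sp in enumerate(sorted(tree.leaves)):
        cl = species_clade[sp]
        if cl == outgroup:
            profiles[sp] = set(full_sorted)
            continue
        p_loss = cfg.ec_loss_prob.get(cl, 0.0) if cl is not None else 0.0
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_EC, s)))
        keep = rng.random(len(full_sorted)) >= p_loss
        profiles[sp] = {ec for ec, k in zip(full_sorted, keep) if k}
    return profiles


# -- demo tree and pathway table --------------------------------------------


def _coalesce(names: list[str], rng: np.random.Generator, mean_wait: float = 10.0):
    """Random ultrametric subtree over ``names``; returns (newick core, age)."""
    items: list[tuple[str, float]] = [(nm, 0.0) for nm in names]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, aa) = items.pop(j)
        (nb, ab) = items.pop(i)
        age = max(aa, ab) + rng.exponential(mean_wait)
        core = f"({na}:{age - aa:.6f},{nb}:{age - ab:.6f})"
        items.append((core, age))
    return items[0]


def simulate_tree(seed: int = 0, n_outgroup: int = 8, n_clade_a: int = 12,
                  n_clade_b: int = 12, total_time_my: float = 500.0
                  ) -> tuple[TimeTree, dict[str, CladeSpec]]:
    """Random time tree shaped like the study design: ((A, B), outgroup).

    Two focal sister clades (named Parasitoida and Aculeata after the groups
    they emulate) plus an early-branching outgroup of sawfly stand-ins.  All
    branch lengths are rescaled so the total tree length is
    ``total_time_my`` (default 500 My).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_TREE,)))
    out_names = [f"SAW{i + 1:02d}" for i in range(n_outgroup)]
    a_names = [f"PAR{i + 1:02d}" for i in range(n_clade_a)]
    b_names = [f"ACU{i + 1:02d}" for i in range(n_clade_b)]
    core_a, age_a = _coalesce(a_names, rng)
    core_b, age_b = _coalesce(b_names, rng)
    core_o, age_o = _coalesce(out_names, rng)
    age_ab = max(age_a, age_b) + rng.exponential(15.0)
    core_ab = f"({core_a}:{age_ab - age_a:.6f},{core_b}:{age_ab - age_b:.6f})"
    age_root = max(age_ab, age_o) + rng.exponential(15.0)
    newick = (
        f"({core_ab}:{age_root - age_ab:.6f},{core_o}:{age_root - age_o:.6f});"
    )
    tree = parse_newick(newick)
    scale = total_time_my / tree.total_length()
    tree = TimeTree(tree.parent, tree.length * scale, tree.leaf_name)
    specs = {
        "Parasitoida": CladeSpec("Parasitoida", "mrca", tuple(a_names)),
        "Aculeata": CladeSpec("Aculeata", "mrca", tuple(b_names)),
        "Outgroup": CladeSpec("Outgroup", "mrca", tuple(out_names)),
    }
    return tree, specs


def balanced_study_tree(n_outgroup: int = 8, n_clade: int = 32,
                        total_time_my: float = 500.0
                        ) -> tuple[TimeTree, dict[str, CladeSpec]]:
    """Deterministic balanced tree for calibration and power studies.

    Two balanced focal clades of ``n_clade`` leaves plus a balanced
    outgroup, every branch the same length, rescaled to ``total_time_my``
    total.  With no random branch-length variation, study outcomes depend
    only on the family-level randomness of the generators, which makes
    power estimates stable across seeds.
    """

    def rec(names, t):
        if len(names) == 1:
            return f"{names[0]}:{t:g}"
        mid = len(names) // 2
        return f"({rec(names[:mid], t)},{rec(names[mid:], t)}):{t:g}"

    a = [f"PAR{i + 1:02d}" for i in range(n_clade)]
    b = [f"ACU{i + 1:02d}" for i in range(n_clade)]
    o = [f"SAW{i + 1:02d}" for i in range(n_outgroup)]
    newick = f"(({rec(a, 1)},{rec(b, 1)}):1,{rec(o, 1)});"
    tree = parse_newick(newick)
    scale = total_time_my / tree.total_length()
    tree = TimeTree(tree.parent, tree.length * scale, tree.leaf_name)
    specs = {
        "Parasitoida": CladeSpec("Parasitoida", "mrca", tuple(a)),
        "Aculeata": CladeSpec("Aculeata", "mrca", tuple(b)),
        "Outgroup": CladeSpec("Outgroup", "mrca", tuple(o)),
    }
    return tree, specs


def simulate_pathways(seed: int = 0, n_pathways: int = 20, n_superpathways: int = 6,
                      ec_pool: int = 150, min_ecs: int = 6, max_ecs: int = 14,
                      reference_prob: float = 0.9) -> pd.DataFrame:
    """Synthetic pathway table: id, superpathway, name, reference flag, EC set."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_TREE, 1)))
    pool = []
    seen = set()
    while len(pool) < ec_pool:
        ec = ".".join(str(int(d)) for d in rng.integers(1, 30, size=4))
        if ec not in seen:
            seen.add(ec)
            pool.append(ec)
    rows = []
    for i in range(n_pathways):
        k = int(rng.integers(min_ecs, max_ecs + 1))
        ecs = sorted(rng.choice(pool, size=k, replace=False))
        rows.append(
            {
                "pathway_id": f"pw{i + 1:03d}",
                "superpathway_id": f"sp{(i % n_superpathways) + 1:02d}",
                "name": f"synthetic pathway {i + 1}",
                "has_reference": bool(rng.random() < reference_prob),
                "ecs": ecs,
            }
        )
    return pd.DataFrame(rows)
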