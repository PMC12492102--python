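"""Gene-family turnover on a time tree.

The central model of the package: ancestral family sizes are reconstructed
by integer-state Sankoff parsimony with linear (optionally asymmetric)
gain/loss costs, per-branch signed count changes are read off the
reconstruction, gain-and-loss rates per My are computed over any branch
scope, and per-(family, branch) events are flagged as rapid when their
magnitude is improbable under a global Poisson turnover null.

Exposed both as plain functions mirroring each operation and as a
statsmodels-style model::

    model = GeneFamilyTurnover(tree, counts)
    res = model.fit(alpha=0.05)
    res.global_rate          # events / My over the whole tree
    res.events               # long table: og_id, branch_id, delta, p_event, rapid
    print(res.summary())

An externally produced event table (e.g. from a likelihood method) can be
wrapped with :meth:`TurnoverResults.from_events` and used with the same
downstream contrasts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tree import TimeTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFamilyTurnover",
    "TurnoverResults",
    "reconstruct_counts",
    "compute_events",
    "gain_loss_rate",
    "flag_rapid_events",
]

_BLOCK = 256  # families per DP block, keeps the state tables small


def _check_counts(tree: TimeTree, counts: pd.DataFrame) -> pd.DataFrame:
    leaves = set(tree.leaves)
    have = set(counts.columns)
    if leaves - have:
        raise ValueError(f"counts missing tree leaves: {sorted(leaves - have)}")
    extra = have - leaves
    if extra:
        raise ValueError(f"count species not in tree: {sorted(extra)}")
    if (counts.values < 0).any():
        raise ValueError("negative family counts")
    return counts[tree.leaves]


def _min_transform(cost: np.ndarray, gain_cost: float, loss_cost: float) -> np.ndarray:
    """min_j cost[:, j] + edge(i, j) for all parent states i, vectorized.

    Edge cost from parent state i to child state j is (j-i)*gain_cost for a
    gain and (i-j)*loss_cost for a loss.  Two sequential passes over the
    state axis compute the full lower envelope in O(states).
    """
    n, s = cost.shape
    up = cost.copy()  # min over j <= i of cost[j] + (i-j)*loss_cost
    for i in range(1, s):
        np.minimum(up[:, i], up[:, i - 1] + loss_cost, out=up[:, i])
    down = cost.copy()  # min over j >= i of cost[j] + (j-i)*gain_cost
    for i in range(s - 2, -1, -1):
        np.minimum(down[:, i], down[:, i + 1] + gain_cost, out=down[:, i])
    return np.minimum(up, down)


def reconstruct_counts(tree: TimeTree, counts: pd.DataFrame, gain_cost: float = 1.0,
                       loss_cost: float = 1.0) -> pd.DataFrame:
    """Sankoff parsimony reconstruction of ancestral family sizes.

    Integer states 0..max(count) with cost ``gain_cost`` per copy gained and
    ``loss_cost`` per copy lost along a branch.  Ties are broken toward the
    smallest admissible state at the root and toward the state closest to
    the parent's assignment (then smallest) below it, so the reconstruction
    is unique and deterministic.

    Returns a families x nodes table; internal nodes are labelled by the
    branch_id of their subtending branch, the root by ``"root"``.
    """
    counts = _check_counts(tree, counts)
    n_fam = len(counts)
    node_labels = [
        tree.leaf_name[v] if tree.is_leaf[v] else (tree.branch_id[v] or "root")
        for v in range(tree.n_nodes)
    ]
    leaf_col = {tree.leaf_name[v]: v for v in range(tree.n_nodes) if tree.is_leaf[v]}
    states = np.zeros((n_fam, tree.n_nodes), dtype=int)
    values = counts.values
    big = np.inf
    for start in range(0, n_fam, _BLOCK):
        block = values[start : start + _BLOCK]
        nb = len(block)
        smax = int(block.max()) if block.size else 0
        s = smax + 1
        grid = np.arange(s)
        cost: list[np.ndarray | None] = [None] * tree.n_nodes
        for v in range(tree.n_nodes):  # post-order
            if tree.is_leaf[v]:
                c = np.full((nb, s), big)
                obs = block[:, counts.columns.get_loc(tree.leaf_name[v])]
                c[np.arange(nb), obs] = 0.0
                cost[v] = c
            else:
                acc = np.zeros((nb, s))
                for ch in tree.children[v]:
                    acc += _min_transform(cost[ch], gain_cost, loss_cost)
                cost[v] = acc
        blk_states = np.zeros((nb, tree.n_nodes), dtype=int)
        root = tree.root
        blk_states[:, root] = np.argmin(cost[root], axis=1)  # first minimum = smallest
        for v in range(tree.n_nodes - 2, -1, -1):  # preorder below root
            p = blk_states[:, tree.parent[v]]
            diff = grid[None, :] - p[:, None]
            edge = np.where(diff > 0, diff * gain_cost, -diff * loss_cost)
            total = cost[v] + edge
            best = total.min(axis=1, keepdims=True)
            # among minimizers: closest to parent, then smallest state
            key = np.where(total <= best + 1e-9, np.abs(diff) * (s + 1) + grid[None, :], np.inf)
            blk_states[:, v] = np.argmin(key, axis=1)
        states[start : start + nb] = blk_states
    return pd.DataFrame(states, index=counts.index.rename("og_id"), columns=node_labels)


def compute_events(tree: TimeTree, ancestral: pd.DataFrame) -> pd.DataFrame:
    """Per-branch signed count change (child minus parent), families x branches."""
    labels = list(ancestral.columns)
    vals = ancestral.values
    branch_ids = tree.branch_ids
    deltas = np.zeros((len(ancestral), len(branch_ids)), dtype=int)
    for i, b in enumerate(branch_ids):
        v = tree.node_of(b)
        p = tree.parent[v]
        deltas[:, i] = vals[:, v] - vals[:, p]
    return pd.DataFrame(deltas, index=ancestral.index, columns=branch_ids)


def gain_loss_rate(deltas: pd.DataFrame, tree: TimeTree, branch_ids=None, og_ids=None,
                   denominator: str = "branch_sum") -> float:
    """Gain-and-loss rate per My over a branch scope and family filter.

    Sum of absolute per-branch count changes divided by the summed branch
    time of the scope (``denominator='branch_sum'``, the default) or by the
    root age (``'root_age'``).  Zero-length branches are excluded from both
    numerator and denominator.
    """
    scope = list(deltas.columns) if branch_ids is None else list(branch_ids)
    usable = [b for b in scope if tree.branch_length(b) > 0]
    skipped = set(scope) - set(usable)
    if skipped:
        logger.info("gain_loss_rate: skipping %d zero-length branches", len(skipped))
    if not usable:
        raise ValueError("empty branch scope (or all branches zero-length)")
    sub = deltas[usable] if og_ids is None else deltas.loc[list(og_ids), usable]
    total_events = float(np.abs(sub.values).sum())
    if denominator == "branch_sum":
        time = float(sum(tree.branch_length(b) for b in usable))
    elif denominator == "root_age":
        time = tree.root_age()
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if time <= 0:
        raise ValueError("scope has zero total time")
    return total_events / time


def flag_rapid_events(deltas: pd.DataFrame, tree: TimeTree, alpha: float = 0.05) -> pd.DataFrame:
    """Long event table with Poisson-tail p-values and rapid flags.

    The null is uniform turnover: the per-family event rate
    ``r = sum |delta| / (n_families * total tree length)`` gives each branch
    an expectation ``lambda = r * t``; an observed change of magnitude d >= 1
    has ``p = P(Poisson(lambda) >= d)``, and is rapid when p < alpha.
    Zero-length branches get p = 1 (no time-based null exists there).
    """
    branch_ids = list(deltas.columns)
    lengths = np.array([tree.branch_length(b) for b in branch_ids])
    total_time = lengths.sum()
    absd = np.abs(deltas.values)
    total_events = absd.sum()
    n_fam = len(deltas)
    p = np.ones_like(absd, dtype=float)
    if total_events > 0 and total_time > 0:
        r_hat = total_events / (n_fam * total_time)
        lam = r_hat * lengths
        active = absd >= 1
        lam_mat = np.broadcast_to(lam, absd.shape)
        p[active] = sps.poisson.sf(absd[active] - 1, lam_mat[active])
        zero_len = np.broadcast_to(lengths == 0, absd.shape)
        p[zero_len] = 1.0
    else:
        logger.info("flag_rapid_events: degenerate null (no events), all p = 1")
    long = pd.DataFrame(
        {
            "og_id": np.repeat(deltas.index.values, len(branch_ids)),
            "branch_id": np.tile(branch_ids, n_fam),
            "delta": deltas.values.ravel(),
            "p_event": p.ravel(),
        }
    )
    long["rapid"] = long["p_event"] < alpha
    return long


class GeneFamilyTurnover:
    """Gene-family turnover model for a count matrix on a time tree.

    Parameters
    ----------
    tree : TimeTree
        Time-calibrated phylogeny; every count-matrix column must be a leaf.
    counts : DataFrame
        Families x species nonnegative integer counts.
    gain_cost, loss_cost : float
        Per-copy parsimony costs (equal by default).
    """

    def __init__(self, tree: TimeTree, counts: pd.DataFrame, gain_cost: float = 1.0,
                 loss_cost: float = 1.0):
        self.tree = tree
        self.counts = _check_counts(tree, counts)
        self.gain_cost = gain_cost
        self.loss_cost = loss_cost

    def fit(self, alpha: float = 0.05, denominator: str = "branch_sum") -> "TurnoverResults":
        ancestral = reconstruct_counts(self.tree, self.counts, self.gain_cost, self.loss_cost)
        deltas = compute_events(self.tree, ancestral)
        events = flag_rapid_events(deltas, self.tree, alpha=alpha)
        return TurnoverResults(self, ancestral, deltas, events, alpha, denominator)


class TurnoverResults:
    """Fitted turnover reconstruction with event flags and rate accessors."""

    def __init__(self, model, ancestral, deltas, events, alpha, denominator="branch_sum"):
        self.model = model
        self.tree: TimeTree = model.tree
        self.ancestral: pd.DataFrame = ancestral
        self.deltas: pd.DataFrame = deltas
        self.events: pd.DataFrame = events
        self.alpha = alpha
        self.denominator = denominator

    @classmethod
    def from_events(cls, tree: TimeTree, events: pd.DataFrame, alpha: float = 0.05):
        """Wrap an externally produced event table (og_id, branch_id, delta
        and optionally p_event/rapid) for use with the same contrasts."""
        ev = events.copy()
        if "p_event" not in ev:
            ev["p_event"] = 1.0
        if "rapid" not in ev:
            ev["rapid"] = ev["p_event"] < alpha
        deltas = ev.pivot(index="og_id", columns="branch_id", values="delta").fillna(0).astype(int)
        deltas = deltas[[b for b in tree.branch_ids if b in deltas.columns]]
        dummy = type("_M", (), {"tree": tree})()
        return cls(dummy, None, deltas, ev, alpha)

    # -- rates -----------------------------------------------------------

    @property
    def global_rate(self) -> float:
        """Genome-wide gain-and-loss events per My (all families, all branches)."""
        return gain_loss_rate(self.deltas, self.tree, denominator=self.denominator)

    @property
    def per_family_rate(self) -> float:
        """Mean per-family turnover rate (events per family per My)."""
        return self.global_rate / len(self.deltas)

    def rate(self, branch_ids=None, og_ids=None) -> float:
        return gain_loss_rate(self.deltas, self.tree, branch_ids, og_ids, self.denominator)

    def branch_rates(self, branch_ids=None) -> pd.DataFrame:
        """Per-family per-branch rates |delta| / t (zero-length branches dropped)."""
        scope = list(self.deltas.columns) if branch_ids is None else list(branch_ids)
        usable = [b for b in scope if self.tree.branch_length(b) > 0]
        t = np.array([self.tree.branch_length(b) for b in usable])
        return self.deltas[usable].abs() / t

    @property
    def n_gains(self) -> int:
        return int(self.deltas.values.clip(min=0).sum())

    @property
    def n_losses(self) -> int:
        return int((-self.deltas.values).clip(min=0).sum())

    # -- contrasts (delegated) -------------------------------------------

    def rapid_enrichment(self, clade_a, clade_b, alpha_fdr: float = 0.05):
        from .contrast import rapid_enrichment

        return rapid_enrichment(self.events, clade_a, clade_b, alpha_fdr)

    def rate_contrast(self, clade_a, clade_b, alternative: str = "greater",
                      alpha_fdr: float = 0.05):
        from .contrast import rate_contrast

        return rate_contrast(self, clade_a, clade_b, alternative, alpha_fdr)

    def summary(self) -> str:
        d = self.deltas.values
        lines = [
            "Gene-family turnover reconstruction",
            "===================================",
            f"families:            {len(self.deltas)}",
            f"branches:            {d.shape[1]}",
            f"total tree time:     {self.tree.total_length():.2f} My",
            f"gains / losses:      {self.n_gains} / {self.n_losses}",
            f"global rate:         {self.global_rate:.4f} events/My ({self.denominator})",
            f"rapid events:        {int(self.events['rapid'].sum())} "
            f"(alpha={self.alpha}, Poisson-tail null)",
        ]
        return "\n".join(lines)
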