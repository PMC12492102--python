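"""Time-calibrated phylogeny container and clade resolution.

The analyses in this package are defined on *branches* of a rooted,
time-calibrated tree (branch lengths in millions of years, My).  Every
non-root node therefore carries a deterministic ``branch_id`` derived from
the sorted set of leaf names below it, so that per-branch tables (gene-count
changes, dN/dS values) produced at different times, or from differently
ordered serializations of the same tree, can always be joined.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree", "CladeSpec", "CladeResolution", "parse_newick", "resolve_clade"]


def _branch_id(leaf_names: tuple[str, ...], chain: int = 0) -> str:
    """Deterministic branch identifier: hash of the sorted descendant leaf set.

    ``chain`` disambiguates nodes on a unary chain (identical leaf sets);
    it is the node's height within that chain, so ids stay invariant under
    leaf-order permutation of the input.
    """
    joined = "\n".join(sorted(leaf_names)) + (f"\n#{chain}" if chain else "")
    return hashlib.sha1(joined.encode()).hexdigest()[:12]


class TimeTree:
    """Rooted phylogeny with nonnegative branch lengths in My.

    Nodes are stored in post-order (children before parents; the root is
    last).  ``parent[i]`` is the post-order index of node *i*'s parent
    (-1 for the root), ``length[i]`` its subtending branch length, and
    ``branch_id[i]`` the stable identifier of that branch (``None`` for the
    root).  Polytomies are kept as-is: all statistics downstream are defined
    per branch, not per bifurcation.
    """

    def __init__(self, parent, length, leaf_name):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        n = len(self.parent)
        if n == 0 or (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        if self.parent[-1] != -1:
            raise ValueError("nodes must be in post-order with the root last")
        if np.any(self.length[:-1] < 0):
            raise ValueError("negative branch length")
        self.n_nodes = n
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        self.leaf_name: list[str | None] = list(leaf_name)
        names = [nm for nm in self.leaf_name if nm is not None]
        if len(names) != int(self.is_leaf.sum()):
            raise ValueError("every leaf needs a name")
        if len(set(names)) != len(names):
            dupes = sorted({nm for nm in names if names.count(nm) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        # leaf sets and branch ids, bottom-up
        self._leafset: list[tuple[str, ...]] = [() for _ in range(n)]
        for i in range(n):
            if self.is_leaf[i]:
                self._leafset[i] = (self.leaf_name[i],)
            else:
                acc: list[str] = []
                for c in self.children[i]:
                    acc.extend(self._leafset[c])
                self._leafset[i] = tuple(sorted(acc))
        chain = [0] * n
        for i in range(n):
            kids = self.children[i]
            if len(kids) == 1 and self._leafset[kids[0]] == self._leafset[i]:
                chain[i] = chain[kids[0]] + 1
        self.branch_id: list[str | None] = [
            _branch_id(self._leafset[i], chain[i]) if self.parent[i] >= 0 else None
            for i in range(n)
        ]
        self._id_to_node = {b: i for i, b in enumerate(self.branch_id) if b is not None}
        if len(self._id_to_node) != n - 1:
            raise ValueError("branch id collision")  # pragma: no cover
        self._name_to_node = {self.leaf_name[i]: i for i in range(n) if self.is_leaf[i]}

    # -- basic queries ---------------------------------------------------

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[str]:
        return [self.leaf_name[i] for i in range(self.n_nodes) if self.is_leaf[i]]

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def branch_ids(self) -> list[str]:
        """All branch ids, post-order (excludes the root)."""
        return [b for b in self.branch_id if b is not None]

    def total_length(self) -> float:
        return float(self.length[self.parent >= 0].sum())

    def root_age(self) -> float:
        """Maximum root-to-leaf path length (tree height in My)."""
        depth = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):
            depth[i] = depth[self.parent[i]] + self.length[i]
        return float(depth[self.is_leaf].max())

    def node_of(self, branch_id: str) -> int:
        return self._id_to_node[branch_id]

    def branch_length(self, branch_id: str) -> float:
        return float(self.length[self._id_to_node[branch_id]])

    def leafset(self, branch_id: str) -> tuple[str, ...]:
        return self._leafset[self._id_to_node[branch_id]]

    def mrca(self, names) -> int:
        """Post-order index of the most recent common ancestor of ``names``."""
        missing = sorted(set(names) - set(self._name_to_node))
        if missing:
            raise KeyError(f"leaves not in tree: {missing}")
        nodes = {self._name_to_node[nm] for nm in names}
        # the MRCA is the lowest node whose leaf set contains all names
        want = set(names)
        for i in range(self.n_nodes):
            if want <= set(self._leafset[i]):
                return i
        return self.root  # pragma: no cover - root always satisfies

    def subtree_nodes(self, node: int) -> list[int]:
        """Post-order indices of all nodes strictly below ``node`` plus itself."""
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return sorted(out)

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if self.is_leaf[i]:
                core = self.leaf_name[i]
            else:
                # deterministic child order: by sorted leaf set
                kids = sorted(self.children[i], key=lambda c: self._leafset[c])
                core = "(" + ",".join(render(c) for c in kids) + ")"
            if self.parent[i] >= 0:
                return f"{core}:{self.length[i]:.17g}"
            return core

        return render(self.root) + ";"


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string (branch lengths required) into a :class:`TimeTree`.

    Raises ``ValueError`` naming the offending position for malformed input
    and for duplicate leaf names.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    parent: list[int] = []
    length: list[float] = []
    names: list[str | None] = []
    index: dict[int, int] = {}
    post = list(dtree.postorder_node_iter())
    for node in post:
        index[id(node)] = len(parent)
        parent.append(-1)
        length.append(node.edge.length if node.edge.length is not None else 0.0)
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise ValueError("unnamed leaf in Newick input")
            names.append(label)
        else:
            names.append(None)
    for node in post:
        for child in node.child_nodes():
            parent[index[id(child)]] = index[id(node)]
    return TimeTree(parent, length, names)


@dataclass
class CladeSpec:
    """Named clade: either the MRCA of >=2 leaves, or an explicit leaf list."""

    name: str
    kind: str = "mrca"  # "mrca" | "leaf_list"
    leaves: tuple[str, ...] = ()
    include_stem: bool = False

    def __post_init__(self):
        if self.kind not in ("mrca", "leaf_list"):
            raise ValueError(f"clade {self.name}: unknown kind {self.kind!r}")
        if self.kind == "mrca" and len(self.leaves) < 2:
            raise ValueError(f"clade {self.name}: mrca spec needs >=2 leaves")
        self.leaves = tuple(self.leaves)


@dataclass(frozen=True)
class CladeResolution:
    """A clade resolved against a tree: its leaves, branches, and total time."""

    name: str
    species: frozenset[str]
    branch_ids: frozenset[str]
    total_time_my: float
    nodes: tuple[int, ...] = field(default=(), repr=False)


def resolve_clade(tree: TimeTree, spec: CladeSpec) -> CladeResolution:
    """Resolve ``spec`` to (leaf set, branch set, summed branch time).

    For an ``mrca`` spec the branch set is every branch in the subtree below
    the MRCA of the named leaves, plus the stem branch iff ``include_stem``.
    For a ``leaf_list`` spec it is every branch whose descendant leaves are
    all within the listed set (the maximal collection of subtrees contained
    in the list), which degrades gracefully for non-monophyletic lists.
    """
    missing = sorted(set(spec.leaves) - set(tree.leaves))
    if missing:
        raise KeyError(f"clade {spec.name}: leaves not in tree: {missing}")
    if spec.kind == "mrca":
        anc = tree.mrca(spec.leaves)
        nodes = [v for v in tree.subtree_nodes(anc) if v != anc]
        if spec.include_stem and tree.parent[anc] >= 0:
            nodes.append(anc)
        species = frozenset(tree._leafset[anc])
    else:
        want = set(spec.leaves)
        nodes = [
            i
            for i in range(tree.n_nodes)
            if tree.parent[i] >= 0 and set(tree._leafset[i]) <= want
        ]
        species = frozenset(spec.leaves)
    branch_ids = frozenset(tree.branch_id[v] for v in nodes)
    total = float(tree.length[nodes].sum()) if nodes else 0.0
    return CladeResolution(spec.name, species, branch_ids, total, tuple(sorted(nodes)))
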