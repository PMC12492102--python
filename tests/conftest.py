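import numpy as np
import pandas as pd
import pytest

from hymevol import parse_newick, resolve_clade, simulate_tree


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_leaf():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def demo_tree():
    """32-leaf demo tree with resolved clades (Parasitoida/Aculeata/Outgroup)."""
    tree, specs = simulate_tree(seed=1)
    clades = {name: resolve_clade(tree, s) for name, s in specs.items()}
    return tree, clades


def random_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with integer-ish branch lengths, for oracle tests."""
    items = [(f"L{i}", 0.0) for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, aa) = items.pop(j)
        (nb, ab) = items.pop(i)
        age = max(aa, ab) + float(rng.integers(1, 5))
        core = f"({na}:{age - aa:g},{nb}:{age - ab:g})"
        items.append((core, age))
    return parse_newick(items[0][0] + ";")


def random_counts(rng: np.random.Generator, tree, n_families: int, max_count: int = 5):
    data = rng.integers(0, max_count + 1, size=(n_families, tree.n_leaves))
    return pd.DataFrame(data, index=[f"og{i}" for i in range(n_families)],
                        columns=tree.leaves)
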