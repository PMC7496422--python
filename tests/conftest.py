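import numpy as np
import pytest

from wgdplacer import parse_newick, parse_species_tree
from wgdplacer.synthetic_data import DEFAULT_SPECIES_TREE


@pytest.fixture(scope="session")
def species_tree():
    """The bundled 8-taxon desk-scale species tree (Ks branch lengths)."""
    return parse_species_tree(DEFAULT_SPECIES_TREE)


def random_gene_tree_newick(rng, max_leaves=12, max_taxa=6,
                            with_supports=True, min_leaves=2) -> str:
    """Random binary gene tree with repeated taxa, supports, Ks lengths."""
    n_leaves = int(rng.integers(min_leaves, max_leaves + 1))
    n_taxa = int(rng.integers(1, max_taxa + 1))
    taxa = [f"T{i}" for i in range(1, n_taxa + 1)]
    leaves = []
    for g in range(1, n_leaves + 1):
        taxon = taxa[int(rng.integers(0, n_taxa))]
        leaves.append(f"{taxon}|g{g}:{rng.uniform(0.01, 0.5):.6f}")
    nodes = leaves[:]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        if len(nodes) == 0:
            nodes.append(f"({a},{b})")
        else:
            sup = ""
            if with_supports and rng.random() < 0.8:
                sup = f"{int(rng.integers(0, 101))}"
            nodes.append(f"({a},{b}){sup}:{rng.uniform(0.01, 0.5):.6f}")
    return nodes[0] + ";"


def random_species_tree_newick(rng, n_taxa=8) -> str:
    nodes = [f"S{i}:{rng.uniform(0.05, 0.5):.6f}" for i in range(1, n_taxa + 1)]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        tail = "" if len(nodes) == 0 else f":{rng.uniform(0.05, 0.5):.6f}"
        nodes.append(f"({a},{b}){tail}")
    return nodes[0] + ";"


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def make_gene_tree():
    def _make(text, **kw):
        return parse_newick(text, **kw)

    return _make
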