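import numpy as np
import pytest

from metapep.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture
def chain_tree():
    """root -> d -> p -> c: a single lineage chain."""
    return TaxonomyTree(
        [
            TaxonNode("root", "root", "root", "root"),
            TaxonNode("d", "root", "domain", "DomainD"),
            TaxonNode("p", "d", "phylum", "PhylumP"),
            TaxonNode("c", "p", "class", "ClassC"),
        ]
    )


@pytest.fixture
def small_tree():
    """Two domains; one family with two genera, plus a lone genus."""
    return TaxonomyTree(
        [
            TaxonNode("root", "root", "root", "root"),
            TaxonNode("bact", "root", "domain", "Bacteria"),
            TaxonNode("fung", "root", "domain", "Fungi"),
            TaxonNode("fam1", "bact", "family", "Bacillaceae"),
            TaxonNode("gen1", "fam1", "genus", "Bacillus"),
            TaxonNode("gen2", "fam1", "genus", "Oceanobacillus"),
            TaxonNode("fam2", "fung", "family", "Aspergillaceae"),
            TaxonNode("gen3", "fam2", "genus", "Aspergillus"),
        ]
    )


def random_tree(n_nodes: int, seed: int) -> TaxonomyTree:
    """Random rooted tree; each non-root node attaches to an earlier node."""
    rng = np.random.default_rng(seed)
    nodes = [TaxonNode("t0", "t0", "root", "t0")]
    for i in range(1, n_nodes):
        parent = f"t{rng.integers(0, i)}"
        nodes.append(TaxonNode(f"t{i}", parent, "no-rank", f"t{i}"))
    return TaxonomyTree(nodes)


def lca_oracle(tree: TaxonomyTree, taxa) -> str:
    """Brute force: intersect explicit root-paths, take last common node."""
    paths = [[tid for _, tid in tree.lineage(t)] for t in taxa]
    common = None
    for path in paths:
        common = set(path) if common is None else common & set(path)
    return [tid for tid in paths[0] if tid in common][-1]
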