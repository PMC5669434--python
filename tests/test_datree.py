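"""Nei DA distances, neighbor joining, and locus-bootstrap supports."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest

from ystrpop.distance import DistanceMatrix
from ystrpop.datree import (
    bootstrap_njtree,
    da_matrix,
    nei_da,
    neighbor_joining,
    path_length_matrix,
    tree_bipartitions,
)
from ystrpop.forensic import FrequencyTable


def freq_table(**loci):
    """FrequencyTable from {locus: {allele: count}} keyword mappings."""
    counts = {l: Counter(c) for l, c in loci.items()}
    return FrequencyTable(
        counts=counts, n_typed={l: sum(c.values()) for l, c in counts.items()}
    )


def test_da_zero_for_identical_tables():
    t = freq_table(L1={"14": 3, "15": 1}, L2={"12": 4})
    assert nei_da(t, t) == pytest.approx(0.0, abs=1e-12)


def test_da_one_for_disjoint_allele_sets():
    a = freq_table(L1={"14": 2}, L2={"12": 2})
    b = freq_table(L1={"16": 2}, L2={"10": 2})
    assert nei_da(a, b) == pytest.approx(1.0)


def test_da_hand_computed_single_locus():
    a = freq_table(L1={"A": 4})
    b = freq_table(L1={"A": 1, "B": 3})
    assert nei_da(a, b) == pytest.approx(0.5)  # 1 - sqrt(0.25)


def test_da_symmetric_and_bounded():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = freq_table(L1=dict(zip("abcd", rng.integers(1, 5, 4))),
                       L2=dict(zip("wxyz", rng.integers(1, 5, 4))))
        b = freq_table(L1=dict(zip("abce", rng.integers(1, 5, 4))),
                       L2=dict(zip("wxyv", rng.integers(1, 5, 4))))
        d1, d2 = nei_da(a, b), nei_da(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert -1e-12 <= d1 <= 1.0 + 1e-12


def test_da_rejects_disjoint_locus_sets():
    with pytest.raises(ValueError):
        nei_da(freq_table(L1={"14": 1}), freq_table(L2={"14": 1}))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxa_solved_exactly():
    d = DistanceMatrix(list("ABC"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    tree = neighbor_joining(d)
    assert np.abs(path_length_matrix(tree.graph, tree.taxa).values - d.values).max() < 1e-12


def test_additive_four_taxon_matrix_recovered():
    d = DistanceMatrix(
        list("ABCD"),
        np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float),
    )
    tree = neighbor_joining(d)
    assert tree_bipartitions(tree.graph, tree.taxa) == {frozenset("CD")}
    recon = path_length_matrix(tree.graph, tree.taxa)
    assert np.abs(recon.values - d.values).max() < 1e-9
    internal = [
        data["length"]
        for u, v, data in tree.graph.edges(data=True)
        if str(u).startswith("_nj") and str(v).startswith("_nj")
    ]
    assert internal == [pytest.approx(2.0)]


def _random_tree_distances(rng, n_taxa):
    """Random binary-ish tree with random branch lengths -> its additive
    leaf distance matrix (the generating truth for NJ)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    g = nx.Graph()
    nodes = list(taxa)
    nxt = 0
    while len(nodes) > 2:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        u = f"i{nxt}"
        nxt += 1
        g.add_edge(a, u, length=rng.uniform(0.1, 1.0))
        g.add_edge(b, u, length=rng.uniform(0.1, 1.0))
        nodes.append(u)
    g.add_edge(nodes[0], nodes[1], length=rng.uniform(0.1, 1.0))
    return g, taxa


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(123)
    for _ in range(50):
        n_taxa = int(rng.integers(6, 11))
        g, taxa = _random_tree_distances(rng, n_taxa)
        d = path_length_matrix(g, taxa)
        tree = neighbor_joining(d)
        recon = path_length_matrix(tree.graph, taxa)
        assert np.abs(recon.values - d.values).max() < 1e-9
        assert tree_bipartitions(tree.graph, taxa) == tree_bipartitions(g, taxa)


def test_newick_agrees_with_dendropy_path_lengths():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(9)
    g, taxa = _random_tree_distances(rng, 7)
    d = path_length_matrix(g, taxa)
    tree = neighbor_joining(d)
    dt = dendropy.Tree.get(data=tree.newick, schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            ta = pdm.taxon_namespace.get_taxon(a)
            tb = pdm.taxon_namespace.get_taxon(b)
            assert pdm.distance(ta, tb) == pytest.approx(d.get(a, b), abs=1e-6)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _cluster_tables(rng, shift):
    """Five populations: two well separated clusters of allele frequencies."""
    tables = {}
    for i in range(5):
        offset = 0 if i < 3 else shift
        loci = {}
        for l in range(8):
            base = 10 + offset + (rng.integers(0, 2))
            loci[f"L{l+1}"] = {str(base): 3, str(base + 1): 1}
        tables[f"pop{i}"] = freq_table(**loci)
    return tables


def test_separating_split_gets_high_support():
    rng = np.random.default_rng(21)
    tables = _cluster_tables(rng, shift=8)
    res = bootstrap_njtree(tables, n_replicates=1000, rng_seed=77)
    split = frozenset({"pop3", "pop4"})
    assert res.bootstrap_supports[split] >= 95.0


def test_single_replicate_supports_are_zero_or_hundred():
    rng = np.random.default_rng(22)
    tables = _cluster_tables(rng, shift=8)
    res = bootstrap_njtree(tables, n_replicates=1, rng_seed=5)
    assert set(res.bootstrap_supports.values()) <= {0.0, 100.0}


def test_identical_tables_flagged_degenerate():
    t = freq_table(L1={"14": 2, "15": 2}, L2={"12": 4})
    res = bootstrap_njtree({"a": t, "b": t, "c": t}, n_replicates=10, rng_seed=0)
    assert res.degenerate


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(23)
    tables = _cluster_tables(rng, shift=6)
    r1 = bootstrap_njtree(tables, n_replicates=50, rng_seed=3)
    r2 = bootstrap_njtree(tables, n_replicates=50, rng_seed=3)
    assert r1.bootstrap_supports == r2.bootstrap_supports
    assert r1.newick == r2.newick
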