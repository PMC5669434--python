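"""Median-joining networks, MP pruning, and the rho TMRCA clock."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_haplotype
from ystrpop.alleles import AlleleValue
from ystrpop.core import Haplotype
from ystrpop.mjnet import (
    MJNetwork,
    MutationModel,
    NetworkConfig,
    build_mj_network,
    mp_postprocess,
    rho_tmrca,
    suggest_ancestral_node,
)


def test_two_haplotypes_single_edge():
    net = build_mj_network(
        [make_haplotype("a", (14, 12)), make_haplotype("b", (15, 12))]
    )
    assert net.median_nodes == []
    assert list(net.graph.edges(data="length")) == [((14, 12), (15, 12), 1)]


def exhaustive_steiner_cost(vectors):
    """Oracle: cheapest connected structure over the observed vectors plus
    any subset of lattice points in their bounding box (total MST length)."""
    vectors = [tuple(v) for v in vectors]
    lo = [min(v[i] for v in vectors) for i in range(len(vectors[0]))]
    hi = [max(v[i] for v in vectors) for i in range(len(vectors[0]))]
    lattice = [
        p
        for p in itertools.product(*[range(l, h + 1) for l, h in zip(lo, hi)])
        if p not in vectors
    ]

    def mst_len(nodes):
        g = nx.Graph()
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                g.add_edge(a, b, weight=sum(abs(x - y) for x, y in zip(a, b)))
        return sum(
            d["weight"]
            for _, _, d in nx.minimum_spanning_tree(g).edges(data=True)
        )

    best = mst_len(vectors)
    for r in range(1, 3):
        for extra in itertools.combinations(lattice, r):
            best = min(best, mst_len(vectors + list(extra)))
    return best


def test_median_vector_beats_spanning_tree():
    """The classic three-haplotype case: one median vector (the
    coordinate-wise median) connects all three at total cost 3 < 4."""
    haps = [
        make_haplotype("a", (14, 12, 10)),
        make_haplotype("b", (15, 13, 10)),
        make_haplotype("c", (14, 13, 11)),
    ]
    net = build_mj_network(haps)
    assert net.median_nodes == [(14, 13, 10)]
    assert net.total_length == 3
    assert net.total_length == exhaustive_steiner_cost(
        [(14, 12, 10), (15, 13, 10), (14, 13, 11)]
    )
    for obs in net.observed_nodes:
        assert net.graph.has_edge(obs, (14, 13, 10))


def test_mp_leaves_optimal_network_unchanged():
    haps = [
        make_haplotype("a", (14, 12, 10)),
        make_haplotype("b", (15, 13, 10)),
        make_haplotype("c", (14, 13, 11)),
    ]
    net = build_mj_network(haps, NetworkConfig(mp_postprocess=False))
    pruned = mp_postprocess(net)
    assert set(pruned.graph.nodes) == set(net.graph.nodes)
    assert pruned.total_length == net.total_length


def test_mp_removes_degree_one_median():
    g = nx.Graph()
    g.add_node((10,), is_median=False, multiplicity=2, populations={}, samples=[])
    g.add_node((12,), is_median=False, multiplicity=1, populations={}, samples=[])
    g.add_node((14,), is_median=True, multiplicity=0, populations={}, samples=[])
    g.add_edge((10,), (12,), length=2)
    g.add_edge((12,), (14,), length=2)
    net = MJNetwork(graph=g, loci=["L1"], weights=np.ones(1, int))
    pruned = mp_postprocess(net)
    assert (14,) not in pruned.graph
    assert nx.is_connected(pruned.graph)


def test_duplicates_collapse_with_multiplicity():
    haps = [
        make_haplotype("a", (14, 12), population="X"),
        make_haplotype("b", (14, 12), population="Y"),
        make_haplotype("c", (15, 12), population="X"),
    ]
    net = build_mj_network(haps)
    assert net.multiplicity((14, 12)) == 2
    assert dict(net.graph.nodes[(14, 12)]["populations"]) == {"X": 1, "Y": 1}


def test_irregular_haplotypes_removed_before_building():
    haps = [
        make_haplotype("a", (14, 12)),
        make_haplotype("b", (15, 12)),
        Haplotype("c", "P", {"L1": AlleleValue.microvariant(14, 2), "L2": AlleleValue.integer(12)}),
        Haplotype("d", "P", {"L1": AlleleValue.null(), "L2": AlleleValue.integer(12)}),
    ]
    net = build_mj_network(haps)
    assert sorted(sid for sid, _ in net.removed) == ["c", "d"]
    assert sum(net.multiplicity(n) for n in net.observed_nodes) == 2


def test_fewer_than_two_distinct_haplotypes_rejected():
    with pytest.raises(ValueError, match="distinct"):
        build_mj_network([make_haplotype("a", (14,)), make_haplotype("b", (14,))])


def test_network_connected_and_never_longer_than_mst():
    rng = np.random.default_rng(8)
    vecs = [tuple(rng.integers(10, 14, 4)) for _ in range(12)]
    haps = [make_haplotype(f"s{i}", v) for i, v in enumerate(vecs)]
    net = build_mj_network(haps)
    assert nx.is_connected(net.graph)
    distinct = sorted(set(vecs))
    g = nx.Graph()
    for i, a in enumerate(distinct):
        for b in distinct[i + 1:]:
            g.add_edge(a, b, weight=sum(abs(x - y) for x, y in zip(a, b)))
    mst_total = sum(
        d["weight"] for _, _, d in nx.minimum_spanning_tree(g).edges(data=True)
    )
    spanning = nx.minimum_spanning_tree(net.graph, weight="length")
    assert sum(d["length"] for _, _, d in spanning.edges(data=True)) <= mst_total


# ---------------------------------------------------------------------------
# rho / TMRCA
# ---------------------------------------------------------------------------

def star_network(path_lengths, n_loci=8):
    g = nx.Graph()
    g.add_node("anc", is_median=True, multiplicity=0)
    for i, d in enumerate(path_lengths):
        g.add_node(f"d{i}", is_median=False, multiplicity=1)
        g.add_edge("anc", f"d{i}", length=d)
    return MJNetwork(graph=g, loci=[f"L{i}" for i in range(n_loci)],
                     weights=np.ones(n_loci, int))


def test_rho_zero_when_all_descendants_identical():
    net = star_network([0, 0, 0])
    est = rho_tmrca(net, "anc")
    assert est.rho == 0.0
    assert est.t_years == 0.0


def test_rho_hand_example_and_year_conversion():
    net = star_network([1, 1, 2, 0], n_loci=8)
    est = rho_tmrca(net, "anc", MutationModel(), "genealogical")
    assert est.rho == pytest.approx(1.0)
    assert est.t_years == pytest.approx(25 * 1.0 / (8 * 0.00267), rel=1e-9)
    assert est.t_years == pytest.approx(1170.4, abs=0.1)


def test_rate_ratio_is_exact_for_any_network():
    net = star_network([3, 1, 4, 1, 5], n_loci=11)
    g = rho_tmrca(net, "anc", MutationModel(), "genealogical")
    e = rho_tmrca(net, "anc", MutationModel(), "evolutionary")
    assert e.t_years / g.t_years == pytest.approx(0.00267 / 0.00069, rel=1e-12)


def test_rho_respects_multiplicities():
    g = nx.Graph()
    g.add_node("anc", is_median=True, multiplicity=0)
    g.add_node("x", is_median=False, multiplicity=3)
    g.add_node("y", is_median=False, multiplicity=1)
    g.add_edge("anc", "x", length=2)
    g.add_edge("anc", "y", length=6)
    net = MJNetwork(graph=g, loci=["L1"], weights=np.ones(1, int))
    est = rho_tmrca(net, "anc")
    # expanded copies: distances {2,2,2,6} -> rho = 3
    assert est.rho == pytest.approx((3 * 2 + 6) / 4)
    assert est.n_descendants == 4


def test_unknown_ancestor_and_single_node_rejected():
    net = star_network([1, 2])
    with pytest.raises(KeyError):
        rho_tmrca(net, "nope")
    g = nx.Graph()
    g.add_node("only", is_median=False, multiplicity=1)
    lonely = MJNetwork(graph=g, loci=["L1"], weights=np.ones(1, int))
    with pytest.raises(ValueError):
        rho_tmrca(lonely, "only")


def test_central_node_heuristic_prefers_hub():
    haps = (
        [make_haplotype(f"h{i}", (14, 12)) for i in range(5)]
        + [make_haplotype("a", (15, 12)), make_haplotype("b", (13, 12)),
           make_haplotype("c", (14, 13))]
    )
    net = build_mj_network(haps)
    assert suggest_ancestral_node(net) == (14, 12)
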