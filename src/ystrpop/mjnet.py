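"""Median-joining haplotype networks and rho-based TMRCA estimation.

A median-joining network connects observed haplotypes (as integer repeat
vectors under a weighted single-step distance) through inferred median
vectors: starting from the minimum-spanning network, coordinate-wise
medians of partially linked triplets are added whenever they reduce the
cost of connecting the triplet, until closure (Bandelt's construction; the
epsilon parameter relaxes which candidate medians are admitted, epsilon=0
being the strictest). Maximum-parsimony post-processing then prunes median
vectors that no minimum-total-length spanning substructure uses.

The rho statistic is the average mutational distance from a designated
ancestral node to every observed haplotype copy; dividing by the total
mutation rate of the panel converts it to generations and calendar years:
``t = rho / (L * mu)`` generations, times the generation time in years.
Two conventional per-locus per-generation Y-STR rates are bundled: the
pedigree-derived (genealogical) rate 0.00267 and the phylogenetically
calibrated (evolutionary) rate 0.00069, with a 25-year generation time.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .core import Haplotype
from .panel import DYS385_PAIR

__all__ = [
    "NetworkConfig",
    "MJNetwork",
    "MutationModel",
    "TmrcaEstimate",
    "build_mj_network",
    "mp_postprocess",
    "rho_tmrca",
    "suggest_ancestral_node",
]

log = logging.getLogger(__name__)

Vector = Tuple[int, ...]


@dataclass(frozen=True)
class NetworkConfig:
    """Median-joining construction settings."""

    epsilon: int = 0
    excluded_loci: frozenset = frozenset()
    weights: Dict[str, int] = field(default_factory=dict)
    mp_postprocess: bool = True

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("locus weights must be positive integers")


@dataclass(frozen=True)
class MutationModel:
    """Y-STR mutation rates (per locus per generation) and generation time."""

    rate_genealogical: float = 0.00267
    rate_evolutionary: float = 0.00069
    generation_years: float = 25.0

    def rate(self, label: str) -> float:
        if label == "genealogical":
            return self.rate_genealogical
        if label == "evolutionary":
            return self.rate_evolutionary
        raise KeyError(f"unknown rate label {label!r}")


@dataclass
class MJNetwork:
    """Observed haplotypes plus median vectors, linked by step distances."""

    graph: nx.Graph  # nodes: Vector; attrs multiplicity, populations, is_median
    loci: List[str]
    weights: np.ndarray
    removed: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def observed_nodes(self) -> List[Vector]:
        return [v for v, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> List[Vector]:
        return [v for v, d in self.graph.nodes(data=True) if d["is_median"]]

    @property
    def total_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def multiplicity(self, node: Vector) -> int:
        return self.graph.nodes[node]["multiplicity"]

    def distance(self, a: Vector, b: Vector) -> int:
        return int(np.abs(np.subtract(a, b)).dot(self.weights))


def _step_distance_matrix(vectors: Sequence[Vector], weights: np.ndarray) -> np.ndarray:
    x = np.asarray(vectors, dtype=int)
    diff = np.abs(x[:, None, :] - x[None, :, :])
    return diff.dot(weights)


def _minimax_levels(d: np.ndarray) -> np.ndarray:
    """For every pair, the largest edge weight on their MST path (the
    distance level at which their components merge)."""
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 1))
    # distinct integer vectors are >= 1 step apart, so no zero-weight edges
    mst = minimum_spanning_tree(csr_matrix(d.astype(float))).toarray()
    adj: List[List[Tuple[int, float]]] = [[] for _ in range(n)]
    for i, j in zip(*np.nonzero(mst)):
        w = float(d[i, j])
        adj[i].append((j, w))
        adj[j].append((i, w))
    minimax = np.zeros((n, n))
    for src in range(n):
        stack = [(src, -1, 0.0)]
        while stack:
            node, parent, best = stack.pop()
            minimax[src, node] = best
            for nb, w in adj[node]:
                if nb != parent:
                    stack.append((nb, node, max(best, w)))
    return minimax


def _spanning_network(
    vectors: List[Vector], weights: np.ndarray, epsilon: int
) -> nx.Graph:
    """The epsilon-relaxed minimum-spanning network: edge (u, v) is kept
    iff d(u, v) <= (level at which u's and v's components merge) + epsilon.
    At epsilon=0 this is the union of all minimum spanning trees."""
    d = _step_distance_matrix(vectors, weights)
    minimax = _minimax_levels(d)
    g = nx.Graph()
    g.add_nodes_from(vectors)
    n = len(vectors)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= minimax[i, j] + epsilon:
                g.add_edge(vectors[i], vectors[j], length=int(d[i, j]))
    return g


def _prepare_vectors(
    haplotypes: Sequence[Haplotype], config: NetworkConfig
) -> Tuple[List[str], Dict[Vector, Counter], Dict[Vector, List[str]], List[Tuple[str, str]]]:
    if not haplotypes:
        raise ValueError("no haplotypes given")
    loci = [
        l for l in haplotypes[0].calls if l not in config.excluded_loci
    ]
    groups: Dict[Vector, Counter] = {}
    samples: Dict[Vector, List[str]] = {}
    removed: List[Tuple[str, str]] = []
    for hap in haplotypes:
        reason = None
        vec: List[int] = []
        for locus in loci:
            call = hap.calls[locus]
            if call.is_microvariant:
                reason = f"intermediate allele {call.serialize()} at {locus}"
            elif call.is_multi:
                reason = f"multi-allelic pattern {call.serialize()} at {locus}"
            elif call.is_null:
                reason = f"null allele at {locus}"
            else:
                vec.append(call.repeats)
                continue
            break
        if reason is not None:
            removed.append((hap.sample_id, reason))
            continue
        key = tuple(vec)
        groups.setdefault(key, Counter())[hap.population] += 1
        samples.setdefault(key, []).append(hap.sample_id)
    return loci, groups, samples, removed


def build_mj_network(
    haplotypes: Sequence[Haplotype], config: NetworkConfig = NetworkConfig()
) -> MJNetwork:
    """Construct the median-joining network of a set of haplotypes.

    Haplotypes with a microvariant, a multi-allelic pattern, or a null at
    an included locus are removed first (their step distances are
    undefined) and logged. Duplicate haplotypes collapse into one node
    with a multiplicity and per-population composition.
    """
    loci, groups, samples, removed = _prepare_vectors(haplotypes, config)
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 distinct haplotypes after filtering, got {len(groups)}"
        )
    weights = np.asarray([config.weights.get(l, 1) for l in loci], dtype=int)
    observed = sorted(groups)
    nodes: Set[Vector] = set(observed)

    def dist(a: Vector, b: Vector) -> int:
        return int(np.abs(np.subtract(a, b)).dot(weights))

    # iterate: spanning network -> admit cost-reducing medians -> repeat
    for _ in range(64):
        vectors = sorted(nodes)
        msn = _spanning_network(vectors, weights, config.epsilon)
        candidates: Dict[Vector, int] = {}
        # a triplet with >= 2 links always shares a central node, so it is
        # enough to scan each node's neighbor pairs
        seen: Set[Tuple[Vector, Vector, Vector]] = set()
        for center in vectors:
            nbrs = sorted(msn.neighbors(center))
            for v, w in itertools.combinations(nbrs, 2):
                triple = tuple(sorted((center, v, w)))
                if triple in seen:
                    continue
                seen.add(triple)
                u, v, w = triple
                med = tuple(int(np.median([a, b, c])) for a, b, c in zip(u, v, w))
                if med in nodes:
                    continue
                star = dist(u, med) + dist(v, med) + dist(w, med)
                pairwise = sorted((dist(u, v), dist(u, w), dist(v, w)))
                if star < pairwise[0] + pairwise[1]:  # beats the triple's MST
                    cost = candidates.get(med)
                    if cost is None or star < cost:
                        candidates[med] = star
        if not candidates:
            break
        lam_min = min(candidates.values())
        admitted = {
            m for m, c in candidates.items() if c <= lam_min + config.epsilon
        }
        nodes.update(admitted)
    else:  # pragma: no cover - safety valve
        log.warning("median-joining did not close after 64 passes")

    vectors = sorted(nodes)
    graph = _spanning_network(vectors, weights, config.epsilon)
    for vec in vectors:
        is_median = vec not in groups
        graph.nodes[vec]["is_median"] = is_median
        graph.nodes[vec]["multiplicity"] = (
            0 if is_median else sum(groups[vec].values())
        )
        graph.nodes[vec]["populations"] = groups.get(vec, Counter())
        graph.nodes[vec]["samples"] = samples.get(vec, [])
    net = MJNetwork(graph=graph, loci=loci, weights=weights, removed=removed)
    if config.mp_postprocess:
        net = mp_postprocess(net, epsilon=config.epsilon)
    return net


def _mst_length(vectors: List[Vector], weights: np.ndarray) -> float:
    if len(vectors) < 2:
        return 0.0
    d = _step_distance_matrix(vectors, weights).astype(float)
    return float(minimum_spanning_tree(csr_matrix(d)).sum())


def mp_postprocess(network: MJNetwork, epsilon: int = 0) -> MJNetwork:
    """Maximum-parsimony pruning of superfluous median vectors.

    A median is removed when a spanning structure over the remaining nodes
    is no longer than the best one using it (greedy test by increasing
    degree; a simplification of exact Steiner-tree pruning). Observed
    haplotypes are always preserved and the result stays connected.
    """
    observed = network.observed_nodes
    medians = set(network.median_nodes)
    retained = set(observed) | medians
    changed = True
    while changed:
        changed = False
        current_len = _mst_length(sorted(retained), network.weights)
        for med in sorted(medians & retained, key=lambda m: network.graph.degree(m)):
            without = sorted(retained - {med})
            if _mst_length(without, network.weights) <= current_len:
                retained.discard(med)
                changed = True
                break

    vectors = sorted(retained)
    graph = _spanning_network(vectors, network.weights, epsilon)
    for vec in vectors:
        for attr in ("is_median", "multiplicity", "populations", "samples"):
            graph.nodes[vec][attr] = network.graph.nodes[vec][attr]
    return MJNetwork(
        graph=graph,
        loci=network.loci,
        weights=network.weights,
        removed=network.removed,
    )


@dataclass
class TmrcaEstimate:
    """rho and its conversion to generations and calendar years."""

    rho: float
    se_rho: float
    n_descendants: int
    n_loci: int
    rate_used: str
    rate: float
    t_generations: float
    t_years: float
    se_years: float


def rho_tmrca(
    network: MJNetwork,
    ancestral_node: Vector,
    model: MutationModel = MutationModel(),
    rate_used: str = "genealogical",
) -> TmrcaEstimate:
    """Estimate the TMRCA of a network from a designated ancestral node.

    rho is the multiplicity-weighted mean shortest-path length from the
    ancestral node to every observed haplotype copy (copies coinciding
    with the ancestor contribute 0). The standard error uses the
    star-genealogy approximation ``se = sqrt(rho / n)``; both are converted
    with ``t = rho / (L * mu)`` generations and the model's generation time.
    """
    g = network.graph
    if ancestral_node not in g:
        raise KeyError(f"ancestral node {ancestral_node!r} not in network")
    if g.number_of_nodes() < 2:
        raise ValueError("rho is undefined for a single-node network")
    dist = nx.single_source_dijkstra_path_length(g, ancestral_node, weight="length")
    total = 0.0
    copies = 0
    for node in network.observed_nodes:
        m = network.multiplicity(node)
        total += m * dist[node]
        copies += m
    if copies == 0:
        raise ValueError("network has no observed haplotype copies")
    rho = total / copies
    se_rho = float(np.sqrt(rho / copies))
    rate = model.rate(rate_used)
    L = len(network.loci)
    t_gen = rho / (L * rate)
    t_years = model.generation_years * t_gen
    se_years = model.generation_years * se_rho / (L * rate)
    return TmrcaEstimate(
        rho=rho,
        se_rho=se_rho,
        n_descendants=copies,
        n_loci=L,
        rate_used=rate_used,
        rate=rate,
        t_generations=t_gen,
        t_years=t_years,
        se_years=se_years,
    )


def suggest_ancestral_node(network: MJNetwork) -> Vector:
    """Multiplicity-weighted most central node: the node minimizing the
    weighted sum of shortest-path distances to all observed copies."""
    best = None
    for node in network.graph:
        dist = nx.single_source_dijkstra_path_length(
            network.graph, node, weight="length"
        )
        far = sum(
            network.multiplicity(o) * dist[o] for o in network.observed_nodes
        )
        if best is None or far < best[0]:
            best = (far, node)
    return best[1]
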