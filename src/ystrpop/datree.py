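"""Nei's DA distance, neighbor-joining trees and locus-bootstrap support.

DA is an allele-frequency distance well suited to tree building:
``DA = 1 - (1/L) * sum_loci sum_alleles sqrt(x * y)`` with x, y the relative
allele frequencies of the two populations (alleles absent from one side
contribute 0). Trees are built by the Saitou-Nei neighbor-joining
agglomeration; node support is estimated by bootstrapping loci with
replacement and recomputing the DA matrix and tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .distance import DistanceMatrix
from .forensic import FrequencyTable

__all__ = [
    "nei_da",
    "da_matrix",
    "neighbor_joining",
    "bootstrap_njtree",
    "NJTreeResult",
    "tree_bipartitions",
    "path_length_matrix",
]


def _shared_loci(freq_a: FrequencyTable, freq_b: FrequencyTable) -> List[str]:
    shared = [l for l in freq_a.loci if l in set(freq_b.loci)]
    if not shared:
        raise ValueError("frequency tables share no loci")
    return shared


def nei_da(
    freq_a: FrequencyTable,
    freq_b: FrequencyTable,
    loci: Optional[Sequence[str]] = None,
) -> float:
    """Nei's DA distance between two allele-frequency tables.

    Restricted to the shared loci; L is the shared-locus count. DA is
    symmetric, lies in [0, 1], and is 0 iff the tables agree exactly.
    """
    loci = list(loci) if loci is not None else _shared_loci(freq_a, freq_b)
    total = 0.0
    for locus in loci:
        fa = freq_a.frequencies(locus)
        fb = freq_b.frequencies(locus)
        total += sum(
            np.sqrt(fa[a] * fb[a]) for a in fa.keys() & fb.keys()
        )
    return 1.0 - total / len(loci)


def da_matrix(
    tables: Dict[str, FrequencyTable], loci: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    """Pairwise DA matrix over named frequency tables."""
    labels = list(tables)
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = nei_da(
                tables[labels[i]], tables[labels[j]], loci=loci
            )
    return DistanceMatrix(labels, values)


@dataclass
class NJTreeResult:
    """An unrooted NJ tree with optional bootstrap supports.

    Bipartitions are keyed by the frozenset of taxa on the side *not*
    containing the alphabetically first taxon (a canonical representation
    of an unrooted split); supports are percentages of replicates.
    """

    newick: str
    graph: nx.Graph
    taxa: List[str]
    bootstrap_supports: Dict[FrozenSet[str], float] = field(default_factory=dict)
    n_replicates: int = 0
    degenerate: bool = False


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _canonical_split(side: Set[str], taxa: Sequence[str]) -> FrozenSet[str]:
    anchor = min(taxa)
    if anchor in side:
        side = set(taxa) - side
    return frozenset(side)


def neighbor_joining(matrix: DistanceMatrix) -> NJTreeResult:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels (a cluster is labeled by its smallest leaf).
    Negative branch-length estimates are clamped to 0 with the deficit
    moved to the sister branch.
    """
    taxa = list(matrix.labels)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    g = nx.Graph()
    g.add_nodes_from(taxa)
    # active clusters: node id -> smallest contained leaf label
    active: Dict[object, str] = {t: t for t in taxa}
    d: Dict[Tuple[object, object], float] = {}
    nodes = list(taxa)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            d[frozenset((a, b))] = matrix.get(a, b)

    def dist(a, b) -> float:
        return d[frozenset((a, b))]

    next_id = 0
    while len(active) > 3:
        items = list(active)
        r = len(items)
        row_sums = {a: sum(dist(a, b) for b in items if b is not a) for a in items}
        best = None
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                q = (r - 2) * dist(a, b) - row_sums[a] - row_sums[b]
                key = tuple(sorted((active[a], active[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = dist(a, b)
        la = dab / 2.0 + (row_sums[a] - row_sums[b]) / (2.0 * (r - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        u = f"_nj{next_id}"
        next_id += 1
        g.add_edge(a, u, length=la)
        g.add_edge(b, u, length=lb)
        for c in items:
            if c is a or c is b:
                continue
            d[frozenset((u, c))] = (dist(a, c) + dist(b, c) - dab) / 2.0
        active[u] = min(active[a], active[b])
        del active[a], active[b]

    a, b, c = sorted(active, key=lambda x: active[x])
    center = f"_nj{next_id}"
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2.0
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2.0
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2.0
    for node, ln in ((a, la), (b, lb), (c, lc)):
        g.add_edge(node, center, length=max(ln, 0.0))

    newick = _to_newick(g, taxa, center)
    return NJTreeResult(newick=newick, graph=g, taxa=taxa)


def _to_newick(
    g: nx.Graph,
    taxa: Sequence[str],
    root,
    supports: Optional[Dict[FrozenSet[str], float]] = None,
) -> str:
    taxa_set = set(taxa)

    def leaves_below(node, parent) -> Set[str]:
        out = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur in taxa_set:
                out.add(cur)
            for nb in g.neighbors(cur):
                if nb != par:
                    stack.append((nb, cur))
        return out

    def emit(node, parent) -> str:
        if node in taxa_set:
            return node
        parts = []
        for nb in sorted(g.neighbors(node), key=str):
            if nb == parent:
                continue
            ln = g.edges[node, nb]["length"]
            parts.append(f"{emit(nb, node)}:{ln:.6g}")
        label = ""
        if supports is not None and parent is not None:
            split = _canonical_split(leaves_below(node, parent), taxa)
            if split in supports:
                label = f"{supports[split]:.0f}"
        return f"({','.join(parts)}){label}"

    return emit(root, None) + ";"


def tree_bipartitions(g: nx.Graph, taxa: Sequence[str]) -> Set[FrozenSet[str]]:
    """Non-trivial splits of an unrooted tree, canonically keyed."""
    taxa_set = set(taxa)
    splits: Set[FrozenSet[str]] = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(h, u) if n in taxa_set}
        if 1 < len(side) < len(taxa_set) - 1:
            splits.add(_canonical_split(side, taxa))
    return splits


def path_length_matrix(g: nx.Graph, taxa: Sequence[str]) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (the additivity oracle)."""
    k = len(taxa)
    values = np.zeros((k, k))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(taxa):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = lengths[a][taxa[j]]
    return DistanceMatrix(list(taxa), values)


def bootstrap_njtree(
    tables: Dict[str, FrequencyTable],
    n_replicates: int = 10_000,
    rng_seed: int = 0,
    loci: Optional[Sequence[str]] = None,
) -> NJTreeResult:
    """NJ tree from DA distances with locus-bootstrap support values.

    Each replicate resamples loci with replacement, recomputes the DA
    matrix and NJ tree; the support of an original internal bipartition is
    the percentage of replicates whose tree contains it. Deterministic
    given ``rng_seed``.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 populations")
    labels = list(tables)
    if loci is None:
        loci = list(tables[labels[0]].loci)
        for lab in labels[1:]:
            loci = [l for l in loci if l in set(tables[lab].loci)]
    if len(loci) < 2:
        raise ValueError("bootstrap over loci needs at least 2 shared loci")

    base_matrix = da_matrix(tables, loci=loci)
    degenerate = bool(np.allclose(base_matrix.values, 0.0))
    tree = neighbor_joining(base_matrix)
    splits = tree_bipartitions(tree.graph, tree.taxa)

    rng = np.random.default_rng(rng_seed)
    counts = {s: 0 for s in splits}
    loci_arr = np.asarray(loci, dtype=object)
    for _ in range(n_replicates):
        resampled = loci_arr[rng.integers(0, len(loci), size=len(loci))]
        rep_matrix = da_matrix(tables, loci=list(resampled))
        rep_splits = tree_bipartitions(
            neighbor_joining(rep_matrix).graph, labels
        )
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {
        s: 100.0 * c / n_replicates for s, c in counts.items()
    }
    root = next(n for n in tree.graph if str(n).startswith("_nj"))
    newick = _to_newick(tree.graph, tree.taxa, root, supports=supports)
    return NJTreeResult(
        newick=newick,
        graph=tree.graph,
        taxa=tree.taxa,
        bootstrap_supports=supports,
        n_replicates=n_replicates,
        degenerate=degenerate,
    )
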