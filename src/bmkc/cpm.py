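"""Overlapping module detection by the clique percolation method (CPM).

A k-clique is a complete subgraph on k vertices; two k-cliques are adjacent
when they share k-1 vertices; a k-clique community is the union of all
k-cliques reachable from one another through such adjacency.  Communities
found this way may overlap in vertices, which suits gene modules: a gene can
sit in more than one functional unit.

The construction here uses the standard reduction through maximal cliques:
communities are the connected components of the graph whose nodes are the
maximal cliques of size >= k and whose links join cliques sharing at least
k-1 vertices.  This is equivalent to percolating over every individual
k-clique (any two k-cliques inside one maximal clique share k-1 vertices
already), and far cheaper.

Random-graph percolation diagnostics are included: the critical edge
probability d(k) = 1 / ((k-1) * N^(1/(k-1))) at which giant k-clique
clusters appear, the vertex order parameter phi = N*/N, and the clique
order parameter varphi = L*/L for the largest cluster.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx

from .diffnet import BinaryAdjacency

__all__ = [
    "Clique",
    "ModuleSet",
    "PercolationStats",
    "enumerate_maximal_cliques",
    "kclique_communities",
    "critical_threshold",
    "estimate_total_kcliques",
    "order_parameters",
]

Clique = tuple[str, ...]


@dataclass
class ModuleSet:
    """Overlapping gene communities, each with its constituent cliques.

    ``modules[i]`` is the sorted gene tuple of community ``i``;
    ``cliques_per_module[i]`` holds the maximal cliques (size >= k) whose
    union forms it.  Modules are sorted by decreasing size, then
    lexicographically, for reproducible output.
    """

    modules: list[tuple[str, ...]] = field(default_factory=list)
    cliques_per_module: list[list[Clique]] = field(default_factory=list)
    k: int = 2

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    @property
    def vertex_union(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out.update(m)
        return frozenset(out)


@dataclass
class PercolationStats:
    """Percolation diagnostics of a graph at a given k."""

    n_genes: int
    k: int
    d_k: float
    n_star: int
    phi: float
    l_total: int
    l_star: int
    varphi: float


def _to_graph(a: BinaryAdjacency) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.gene_ids)
    ii, jj = a.values.nonzero()
    g.add_edges_from(
        (a.gene_ids[i], a.gene_ids[j]) for i, j in zip(ii.tolist(), jj.tolist()) if i < j
    )
    return g


def enumerate_maximal_cliques(a: BinaryAdjacency, min_size: int = 1) -> list[Clique]:
    """All maximal cliques (Bron-Kerbosch via networkx), each reported once.

    Members are sorted within each clique and the list is sorted by
    (descending size, lexicographic members).  Isolated vertices appear as
    maximal cliques of size 1 unless ``min_size`` excludes them.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(_to_graph(a)) if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def kclique_communities(a: BinaryAdjacency, k: int) -> ModuleSet:
    """k-clique percolation communities of a binary graph."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    cliques = [frozenset(c) for c in enumerate_maximal_cliques(a, min_size=k)]
    # Union-find over maximal cliques; two are linked when they share >= k-1
    # vertices.  Candidate pairs are generated through shared membership, so
    # disjoint cliques are never compared.
    parent = list(range(len(cliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    membership: dict[str, list[int]] = {}
    for idx, c in enumerate(cliques):
        for v in c:
            membership.setdefault(v, []).append(idx)
    seen: set[tuple[int, int]] = set()
    for idx, c in enumerate(cliques):
        for v in c:
            for jdx in membership[v]:
                if jdx >= idx:
                    continue
                pair = (jdx, idx)
                if pair in seen:
                    continue
                seen.add(pair)
                if len(c & cliques[jdx]) >= k - 1:
                    union(idx, jdx)
    groups: dict[int, list[int]] = {}
    for idx in range(len(cliques)):
        groups.setdefault(find(idx), []).append(idx)
    modules: list[tuple[str, ...]] = []
    per_module: list[list[Clique]] = []
    for members in groups.values():
        genes: set[str] = set()
        for idx in members:
            genes.update(cliques[idx])
        modules.append(tuple(sorted(genes)))
        comp = [tuple(sorted(cliques[idx])) for idx in members]
        comp.sort(key=lambda c: (-len(c), c))
        per_module.append(comp)
    order = sorted(range(len(modules)), key=lambda i: (-len(modules[i]), modules[i]))
    return ModuleSet(
        modules=[modules[i] for i in order],
        cliques_per_module=[per_module[i] for i in order],
        k=k,
    )


def critical_threshold(n_genes: int, k: int) -> float:
    """Critical edge probability d(k) = 1 / ((k-1) * N^(1/(k-1))).

    Above this density a random graph of N nodes develops a giant k-clique
    percolation cluster.  At k = 2 it reduces to the classical 1/N giant
    component threshold.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    return 1.0 / ((k - 1) * n_genes ** (1.0 / (k - 1)))


def estimate_total_kcliques(n_genes: int, k: int, d: float) -> float:
    """Expected k-clique count of a random graph: C(N, k) * d^(k(k-1)/2)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    return math.comb(n_genes, k) * d ** (k * (k - 1) // 2)


def _kcliques_of(maximal: list[Clique], k: int) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()
    for c in maximal:
        for sub in itertools.combinations(c, k):
            out.add(frozenset(sub))
    return out


def order_parameters(a: BinaryAdjacency, k: int) -> PercolationStats:
    """Percolation order parameters of the largest k-clique cluster.

    The largest cluster is the community with the most vertices, ties broken
    by the lexicographically smallest member tuple.  ``l_total`` counts the
    graph's k-cliques exactly; ``varphi`` is defined as 0 when no k-clique
    exists.
    """
    if a.n_genes == 0:
        raise ValueError("order parameters are undefined on an empty graph")
    modules = kclique_communities(a, k)
    l_total = len(_kcliques_of(enumerate_maximal_cliques(a, min_size=k), k))
    if len(modules) == 0:
        n_star, l_star = 0, 0
    else:
        # modules are pre-sorted by (-size, members); the first is the largest
        n_star = len(modules.modules[0])
        l_star = len(_kcliques_of(modules.cliques_per_module[0], k))
    phi = n_star / a.n_genes
    varphi = l_star / l_total if l_total > 0 else 0.0
    return PercolationStats(
        n_genes=a.n_genes,
        k=k,
        d_k=critical_threshold(a.n_genes, k),
        n_star=n_star,
        phi=phi,
        l_total=l_total,
        l_star=l_star,
        varphi=varphi,
    )
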