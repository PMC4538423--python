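"""Shared fixtures and independent oracles.

The brute-force k-clique percolation oracle here enumerates every k-subset
of vertices, keeps the complete ones, and unions them through
shared-(k-1)-vertex adjacency with a union-find — a literal transcription
of the community definition, kept independent of the package's
maximal-clique reduction so the two can be compared.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bmkc import BinaryAdjacency


def adjacency_from_edges(n: int, edges: list[tuple[int, int]], prefix: str = "g") -> BinaryAdjacency:
    """Build a BinaryAdjacency on n vertices named g0..g{n-1} from index pairs."""
    values = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        values[i, j] = values[j, i] = 1
    return BinaryAdjacency(values=values, gene_ids=[f"{prefix}{i}" for i in range(n)])


def complete_adjacency(n: int) -> BinaryAdjacency:
    values = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(values, 0)
    return BinaryAdjacency(values=values, gene_ids=[f"g{i}" for i in range(n)])


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> BinaryAdjacency:
    upper = rng.random((n, n)) < p
    values = np.triu(upper, k=1)
    values = (values | values.T).astype(np.uint8)
    return BinaryAdjacency(values=values, gene_ids=[f"g{i}" for i in range(n)])


def brute_force_kclique_modules(a: BinaryAdjacency, k: int) -> set[frozenset[str]]:
    """Literal k-clique percolation: enumerate k-subsets, test completeness,
    union by shared-(k-1) adjacency via union-find."""
    adj = a.values.astype(bool)
    n = a.n_genes
    kcliques = [
        c
        for c in itertools.combinations(range(n), k)
        if all(adj[i, j] for i, j in itertools.combinations(c, 2))
    ]
    parent = list(range(len(kcliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(kcliques)), 2):
        if len(set(kcliques[i]) & set(kcliques[j])) >= k - 1:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for idx in range(len(kcliques)):
        groups.setdefault(find(idx), set()).update(kcliques[idx])
    return {frozenset(a.gene_ids[v] for v in vertices) for vertices in groups.values()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150803)
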