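"""k-clique percolation on a toy graph, with percolation diagnostics.

Two triangles glued on an edge merge into one community at k = 3; two
triangles sharing only a vertex stay separate (their overlap, one vertex,
is below the k-1 = 2 needed for adjacency), yet they overlap in that gene.
"""

import numpy as np

from bmkc import BinaryAdjacency, critical_threshold, kclique_communities, order_parameters


def graph(n, edges, names):
    values = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        values[i, j] = values[j, i] = 1
    return BinaryAdjacency(values, names)


shared_edge = graph(4, [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)], ["a", "b", "c", "d"])
shared_vertex = graph(5, [(0, 1), (0, 2), (1, 2), (2, 3), (2, 4), (3, 4)], ["a", "b", "c", "d", "e"])

for label, g in (("triangles sharing an edge", shared_edge), ("triangles sharing a vertex", shared_vertex)):
    modules = kclique_communities(g, k=3)
    print(f"{label}: {len(modules)} module(s): {[list(m) for m in modules]}")

stats = order_parameters(shared_vertex, k=3)
print()
print(f"percolation stats (shared-vertex graph, k=3): N*={stats.n_star}, "
      f"phi={stats.phi:.2f}, L={stats.l_total}, L*={stats.l_star}, varphi={stats.varphi:.2f}")
print(f"critical edge probability d(3) for a 120-gene graph: {critical_threshold(120, 3):.4f}")
print()
print("phi is the vertex share of the largest percolation cluster, varphi")
print("its share of the graph's 3-cliques; d(k) is the random-graph edge")
print("density above which giant k-clique clusters are expected.")
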