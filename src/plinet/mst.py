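"""Maximum spanning tree construction and tree topology measures.

The maximum spanning tree (MST) of a dense connectivity matrix is the
acyclic subgraph on all M vertices that maximizes total edge weight — the
backbone of strongest connections.  Because every MST has exactly M
vertices and M−1 edges, tree measures compare networks without the bias a
connection-density difference would introduce; edge weights are discarded
once the tree is built.

Measures (distances counted in edges along the unique tree path):

* **leaf number** — count of degree-1 vertices (centralization index);
* **diameter** — greatest distance between any two vertices;
* **eccentricity** — per vertex, the greatest distance to any other vertex
  (lower = more central);
* **betweenness centrality** — per vertex, the number of unordered vertex
  pairs whose unique connecting path crosses it as an intermediate.

Each measure is normalized by its maximal possible value over trees on M
vertices: M−1 for leaf number, diameter and eccentricity (the star attains
the leaf maximum, the path the diameter/eccentricity maximum) and
(M−1)(M−2)/2 for betweenness (attained by the star's centre).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .weighted_graph import WeightedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "TreeMetrics",
    "maximum_spanning_tree",
    "tree_metrics",
    "normalize_tree_metrics",
]


@dataclass
class Tree:
    """Undirected spanning tree: M vertices, M−1 edges, connected, acyclic."""

    n_vertices: int
    edges: tuple[tuple[int, int], ...]
    vertex_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.edges = tuple(tuple(sorted(e)) for e in self.edges)
        m = self.n_vertices
        if len(self.edges) != m - 1:
            raise ValueError(f"a tree on {m} vertices needs {m - 1} edges")
        parent = list(range(m))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in self.edges:
            if not (0 <= i < m and 0 <= j < m and i != j):
                raise ValueError(f"edge ({i}, {j}) out of range")
            ri, rj = find(i), find(j)
            if ri == rj:
                raise ValueError("edge set contains a cycle")
            parent[ri] = rj
        if self.vertex_labels is not None:
            self.vertex_labels = tuple(self.vertex_labels)
            if len(self.vertex_labels) != m:
                raise ValueError("vertex_labels length mismatch")

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class TreeMetrics:
    """Raw and (optionally) normalized tree topology measures."""

    leaf_number: int
    diameter: int
    eccentricity_per_vertex: np.ndarray
    mean_eccentricity: float
    betweenness_per_vertex: np.ndarray
    max_betweenness: int
    leaf_number_norm: float | None = None
    diameter_norm: float | None = None
    eccentricity_norm: np.ndarray | None = field(default=None, repr=False)
    mean_eccentricity_norm: float | None = None
    betweenness_norm: np.ndarray | None = field(default=None, repr=False)
    max_betweenness_norm: float | None = None


def maximum_spanning_tree(graph: WeightedGraph) -> Tree:
    """Kruskal's algorithm on a symmetric nonnegative weight matrix.

    Edges are scanned in order of (descending weight, ascending vertex
    pair), which makes the result deterministic under weight ties.
    Zero-weight edges are admitted (with a log warning when one is used) so
    that a spanning tree always exists on a dense matrix.
    """
    w = np.asarray(graph.weights, dtype=float)
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("connectivity matrix must be symmetric")
    m = w.shape[0]
    if m < 2:
        raise ValueError("need at least 2 vertices")
    iu, ju = np.triu_indices(m, k=1)
    order = sorted(range(iu.size), key=lambda k: (-w[iu[k], ju[k]], iu[k], ju[k]))

    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int]] = []
    used_zero = False
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        parent[ri] = rj
        edges.append((i, j))
        if w[i, j] == 0.0:
            used_zero = True
        if len(edges) == m - 1:
            break
    if used_zero:
        logger.warning("maximum spanning tree includes zero-weight edges")
    return Tree(n_vertices=m, edges=tuple(edges), vertex_labels=graph.vertex_labels)


def _bfs_distances(adj: list[list[int]], source: int, m: int) -> np.ndarray:
    dist = np.full(m, -1, dtype=int)
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt: list[int] = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def tree_metrics(tree: Tree) -> TreeMetrics:
    """Leaf number, diameter, per-vertex eccentricity and betweenness.

    Betweenness of v counts unordered pairs {u, w} (u, w ≠ v) whose unique
    path passes through v; removing v splits the tree into components of
    sizes c_1..c_d, and the pairs through v are exactly those straddling two
    components: C(M−1, 2) − Σ C(c_i, 2).
    """
    m = tree.n_vertices
    adj = tree.adjacency()
    deg = tree.degrees()
    leaf_number = int(np.sum(deg == 1))

    ecc = np.empty(m, dtype=int)
    for v in range(m):
        ecc[v] = int(_bfs_distances(adj, v, m).max())
    diameter = int(ecc.max())

    # Component sizes of T − v via the subtree sizes of a rooted traversal.
    subtree = np.ones(m, dtype=int)
    root = 0
    parent = np.full(m, -1, dtype=int)
    order: list[int] = []
    stack = [root]
    seen = np.zeros(m, dtype=bool)
    seen[root] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for nb in adj[u]:
            if not seen[nb]:
                seen[nb] = True
                parent[nb] = u
                stack.append(nb)
    for u in reversed(order):
        if parent[u] >= 0:
            subtree[parent[u]] += subtree[u]

    total_pairs = (m - 1) * (m - 2) // 2
    betweenness = np.empty(m, dtype=int)
    for v in range(m):
        comp_sizes = [subtree[nb] for nb in adj[v] if parent[nb] == v]
        if parent[v] >= 0:
            comp_sizes.append(m - subtree[v])
        betweenness[v] = total_pairs - sum(c * (c - 1) // 2 for c in comp_sizes)

    return TreeMetrics(
        leaf_number=leaf_number,
        diameter=diameter,
        eccentricity_per_vertex=ecc,
        mean_eccentricity=float(ecc.mean()),
        betweenness_per_vertex=betweenness,
        max_betweenness=int(betweenness.max()),
    )


def normalize_tree_metrics(metrics: TreeMetrics, m: int) -> TreeMetrics:
    """Fill the normalized fields, dividing each measure by its maximum.

    Leaf number, diameter and eccentricities are divided by M−1; betweenness
    by (M−1)(M−2)/2.  Requires M ≥ 3 so both constants are positive.
    """
    if m < 3:
        raise ValueError("normalization requires at least 3 vertices")
    dist_max = float(m - 1)
    bc_max = (m - 1) * (m - 2) / 2.0
    return TreeMetrics(
        leaf_number=metrics.leaf_number,
        diameter=metrics.diameter,
        eccentricity_per_vertex=metrics.eccentricity_per_vertex,
        mean_eccentricity=metrics.mean_eccentricity,
        betweenness_per_vertex=metrics.betweenness_per_vertex,
        max_betweenness=metrics.max_betweenness,
        leaf_number_norm=metrics.leaf_number / dist_max,
        diameter_norm=metrics.diameter / dist_max,
        eccentricity_norm=metrics.eccentricity_per_vertex / dist_max,
        mean_eccentricity_norm=metrics.mean_eccentricity / dist_max,
        betweenness_norm=metrics.betweenness_per_vertex / bc_max,
        max_betweenness_norm=metrics.max_betweenness / bc_max,
    )
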