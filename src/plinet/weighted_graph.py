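"""Traditional measures on a weighted (dense) brain graph.

Vertices are electrodes; edge weights are PLI values.  Two families of
measures are computed:

* **Clustering.** The intensity of a triangle is the geometric mean of its
  edge weights, each normalized by the maximum weight in the graph.  The
  weighted clustering coefficient of a vertex is the average intensity over
  all triangles in which that vertex participates.  On a dense graph every
  vertex participates in all ``(M−1)(M−2)/2`` triangles through it, with
  zero-weight edges contributing zero-intensity triangles; the global
  coefficient is the mean over vertices.

* **Distance.** The inverse weighted length of a path is the sum of the
  reciprocals of its edge weights; the weighted distance between two
  vertices is the shortest such length over all connecting paths (infinite
  when disconnected; zero-weight entries are treated as absent edges).  The
  weighted characteristic path length is the mean distance over unordered
  pairs of distinct vertices.

For band-profile comparisons, each subject-level measure may additionally be
normalized by its mean over the five canonical frequency bands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedGraph",
    "GraphMeasures",
    "triangle_intensity",
    "weighted_clustering",
    "weighted_distance_matrix",
    "characteristic_path_length",
    "normalize_across_bands",
    "graph_measures",
]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray
    vertex_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.vertex_labels is not None:
            self.vertex_labels = tuple(self.vertex_labels)
            if len(self.vertex_labels) != w.shape[0]:
                raise ValueError("vertex_labels length mismatch")

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphMeasures:
    clustering_per_vertex: np.ndarray
    global_clustering: float
    distance_matrix: np.ndarray
    characteristic_path_length: float


def triangle_intensity(w_ij: float, w_jk: float, w_ki: float, w_max: float) -> float:
    """Geometric mean of the three edge weights, each normalized by ``w_max``."""
    if w_max <= 0:
        raise ValueError("w_max must be positive")
    if min(w_ij, w_jk, w_ki) < 0:
        raise ValueError("edge weights must be nonnegative")
    return float(((w_ij / w_max) * (w_jk / w_max) * (w_ki / w_max)) ** (1.0 / 3.0))


def weighted_clustering(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    """Per-vertex weighted clustering coefficients and their global mean.

    Vertex i's coefficient averages ``triangle_intensity`` over all unordered
    pairs {j, k} of other vertices (dense-graph convention: the denominator is
    ``(M−1)(M−2)/2`` and triangles with a zero edge contribute 0).
    """
    m = graph.n_vertices
    if m < 3:
        raise ValueError("weighted clustering needs at least 3 vertices")
    w_max = float(graph.weights.max())
    if w_max <= 0:
        # Entirely disconnected graph: no triangle has positive intensity.
        return np.zeros(m), 0.0
    a = np.cbrt(graph.weights / w_max)
    # (A^3)_ii sums cbrt-intensity products over ordered pairs (j, k); the
    # diagonal of A is zero so degenerate paths vanish, and /2 de-duplicates.
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    per_vertex = tri / ((m - 1) * (m - 2) / 2.0)
    per_vertex = np.clip(per_vertex, 0.0, 1.0)
    return per_vertex, float(per_vertex.mean())


def weighted_distance_matrix(graph: WeightedGraph) -> np.ndarray:
    """All-pairs shortest inverse-weighted path lengths.

    Edge lengths are reciprocals of the weights; zero-weight entries are
    absent edges.  Unreachable pairs get ``inf``.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(graph.weights > 0, 1.0 / graph.weights, 0.0)
    dist = dijkstra(lengths, directed=False, unweighted=False)
    np.fill_diagonal(dist, 0.0)
    return dist


def characteristic_path_length(distances: np.ndarray) -> float:
    """Mean distance over unordered pairs of distinct vertices (∞ propagates)."""
    d = np.asarray(distances, dtype=float)
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    if np.any(np.isinf(vals)):
        logger.warning("graph is disconnected; characteristic path length is inf")
        return math.inf
    return float(vals.mean())


def normalize_across_bands(
    values: Mapping[str, float],
    bands: Sequence[str] = ("delta", "theta", "lower_alpha", "upper_alpha", "beta"),
) -> dict[str, float]:
    """Divide one subject's per-band values of a measure by their band mean.

    Exactly the expected band set must be present and the mean must be
    positive; the normalized values average to 1 by construction.
    """
    expected = set(bands)
    if set(values) != expected:
        raise ValueError(
            f"expected bands {sorted(expected)}, got {sorted(values)}"
        )
    mean = float(np.mean([values[b] for b in bands]))
    if not mean > 0:
        raise ValueError("band mean must be positive for normalization")
    return {b: float(values[b]) / mean for b in bands}


def graph_measures(graph: WeightedGraph) -> GraphMeasures:
    """Convenience bundle: clustering plus distances for one graph."""
    per_vertex, global_c = weighted_clustering(graph)
    dist = weighted_distance_matrix(graph)
    return GraphMeasures(
        clustering_per_vertex=per_vertex,
        global_clustering=global_c,
        distance_matrix=dist,
        characteristic_path_length=characteristic_path_length(dist),
    )
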