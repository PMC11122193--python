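"""Patch-to-graph conversion.

Each p x p patch becomes an undirected weighted graph on Z = p**2 nodes,
one node per pixel in row-major order. Edge weights are the absolute
intensity difference |v_j - v_i| of the endpoint pixels, so weights live in
[0, 1] and depend only on contrast, not absolute brightness.

Three constructions are supported:

* ``grid2d`` — 4-connected lattice (orthogonal pixel neighbors);
* ``pairwise`` — complete graph on all pixels of the patch;
* ``knn`` — each node proposes its k nearest neighbors in intensity space
  (ties broken by ascending node index), and the edge set is the
  symmetrized union of proposals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "GRAPH_TYPES",
    "PatchGraph",
    "InvalidKError",
    "edge_weight",
    "build_grid2d",
    "build_pairwise",
    "build_knn",
    "build_graph",
]

GRAPH_TYPES = ("grid2d", "pairwise", "knn")


class InvalidKError(ValueError):
    """Raised when the K-NN neighbor count is out of range."""


def edge_weight(v1: float, v2: float) -> float:
    """Absolute intensity difference |v2 - v1| of two normalized pixels."""
    return abs(float(v2) - float(v1))


@dataclass
class PatchGraph:
    """Weighted undirected graph of one image patch.

    Attributes
    ----------
    graph : nx.Graph
        Nodes ``0..Z-1`` in row-major pixel order; edges carry a
        ``weight`` attribute in ``[0, 1]``.
    values : np.ndarray
        Flattened node intensities, length Z.
    graph_type : str
        One of :data:`GRAPH_TYPES`.
    knn_k : int | None
        Neighbor count (knn graphs only).
    """

    graph: nx.Graph
    values: np.ndarray
    graph_type: str
    knn_k: int | None = field(default=None)

    @property
    def n_nodes(self) -> int:
        return len(self.values)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as sorted (i, j, weight) triples with i < j."""
        return sorted(
            (min(i, j), max(i, j), d["weight"])
            for i, j, d in self.graph.edges(data=True)
        )


def _empty_graph(values: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(values)))
    return g


def _add_weighted(g: nx.Graph, values: np.ndarray, i: int, j: int) -> None:
    g.add_edge(i, j, weight=edge_weight(values[i], values[j]))


def build_grid2d(patch: np.ndarray) -> PatchGraph:
    """4-connected lattice graph; |E| = 2 p (p - 1) for a p x p patch."""
    patch = np.asarray(patch, dtype=np.float64)
    p = patch.shape[0]
    values = patch.ravel()
    g = _empty_graph(values)
    for r in range(p):
        for c in range(p):
            i = r * p + c
            if c + 1 < p:
                _add_weighted(g, values, i, i + 1)
            if r + 1 < p:
                _add_weighted(g, values, i, i + p)
    return PatchGraph(g, values, "grid2d")


def build_pairwise(patch: np.ndarray) -> PatchGraph:
    """Complete graph on all Z = p**2 pixels; |E| = Z (Z - 1) / 2."""
    patch = np.asarray(patch, dtype=np.float64)
    values = patch.ravel()
    Z = len(values)
    g = _empty_graph(values)
    for i in range(Z):
        for j in range(i + 1, Z):
            _add_weighted(g, values, i, j)
    return PatchGraph(g, values, "pairwise")


def build_knn(patch: np.ndarray, k: int) -> PatchGraph:
    """K-nearest-neighbor graph in intensity space, symmetrized by union.

    Each node i ranks all other nodes by |v_j - v_i| (ties broken by lower
    node index) and proposes edges to the first k; an edge exists if either
    endpoint proposed it. With k = Z - 1 this is the complete graph.
    """
    patch = np.asarray(patch, dtype=np.float64)
    values = patch.ravel()
    Z = len(values)
    if not 1 <= k <= Z - 1:
        raise InvalidKError(f"k={k} out of range [1, {Z - 1}] for {Z} nodes")
    g = _empty_graph(values)
    for i in range(Z):
        others = [j for j in range(Z) if j != i]
        # stable sort on distance; index order breaks ties deterministically
        others.sort(key=lambda j: (abs(values[j] - values[i]), j))
        for j in others[:k]:
            _add_weighted(g, values, i, j)
    return PatchGraph(g, values, "knn", knn_k=k)


def build_graph(patch: np.ndarray, graph_type: str, knn_k: int | None = None) -> PatchGraph:
    """Dispatch on graph type; ``knn_k`` is required iff type is ``knn``."""
    if graph_type == "grid2d":
        return build_grid2d(patch)
    if graph_type == "pairwise":
        return build_pairwise(patch)
    if graph_type == "knn":
        if knn_k is None:
            raise InvalidKError("knn graph requires knn_k")
        return build_knn(patch, knn_k)
    raise ValueError(f"unknown graph type {graph_type!r}; expected one of {GRAPH_TYPES}")
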