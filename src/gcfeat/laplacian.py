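"""Adjacency, degree and modified weighted Laplacian (MWL) matrices.

The MWL of a patch graph is L = D - A where A is the *weighted* adjacency
(|intensity difference| weights) but D holds *unweighted* degrees (edge
counts). Mixing the two is the modification: since every weight is at most
1 and each row of A has exactly D_ii nonzero slots, each diagonal entry
dominates its row's absolute off-diagonal sum. Dominance is weak in
general and strict whenever some incident weight is below 1; either way
L is symmetric positive semi-definite with integer diagonal.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graphs import PatchGraph

__all__ = [
    "weighted_adjacency",
    "unweighted_adjacency",
    "degree_matrix",
    "mwl",
    "dump_matrix",
]


def weighted_adjacency(g: PatchGraph) -> np.ndarray:
    """Z x Z symmetric matrix; A_ij = |v_j - v_i| for edges, else 0.

    Structural edges between equal-valued pixels are numerically zero here
    but still count toward the degree matrix.
    """
    return nx.to_numpy_array(g.graph, nodelist=range(g.n_nodes), weight="weight")


def unweighted_adjacency(g: PatchGraph) -> np.ndarray:
    """Binary Z x Z matrix; S_ij = 1 iff (i, j) is an edge."""
    return nx.to_numpy_array(g.graph, nodelist=range(g.n_nodes), weight=None)


def degree_matrix(S: np.ndarray) -> np.ndarray:
    """Diagonal matrix of row sums of the unweighted adjacency."""
    S = np.asarray(S)
    return np.diag(S.sum(axis=1))


def mwl(g: PatchGraph) -> np.ndarray:
    """Modified weighted Laplacian L = D - A (unweighted D, weighted A)."""
    A = weighted_adjacency(g)
    D = degree_matrix(unweighted_adjacency(g))
    return D - A


def dump_matrix(L: np.ndarray, precision: int = 6) -> str:
    """Whitespace-delimited text rendering of a matrix, for debugging."""
    return "\n".join(
        " ".join(f"{v:.{precision}g}" for v in row) for row in np.asarray(L)
    )
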