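"""Gershgorin circle feature extraction (GCFE).

Every eigenvalue of a square matrix lies in the union of its Gershgorin
discs: for row i the disc is centered at the diagonal entry c_i with
radius r_i, the absolute sum of the row's off-diagonal entries. For the
modified weighted Laplacian the centers are integer node degrees, the
radii never exceed their center, and the matrix is symmetric — so every
disc is a real interval [c_i - r_i, c_i + r_i] with nonnegative left end.

The (R, C) pair per patch is the reduced representation: a P x N x N stack
of Laplacians collapses to a P x N x 2 feature tensor, where P is the
number of patches and N the number of pixels (nodes) per patch. The total
feature count 2 * P * N = 2 * M * N_img does not depend on the patch size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocessing as pre
from .graphs import GRAPH_TYPES, build_graph
from .laplacian import mwl

__all__ = [
    "GCFeatures",
    "gershgorin_radii",
    "gershgorin_centers",
    "extract",
    "layout_2d",
    "layout_1d",
]


def gershgorin_radii(L: np.ndarray) -> np.ndarray:
    """Per-row absolute off-diagonal sum r_i of a square matrix."""
    L = np.asarray(L, dtype=np.float64)
    return np.abs(L).sum(axis=1) - np.abs(np.diag(L))


def gershgorin_centers(L: np.ndarray) -> np.ndarray:
    """Diagonal entries c_i; for an MWL these are the node degrees."""
    return np.diag(np.asarray(L, dtype=np.float64)).copy()


@dataclass(frozen=True)
class GCFeatures:
    """Per-patch Gershgorin radius/center features of one image.

    ``tensor`` has shape ``(P, N, 2)``: ``tensor[p, :, 0]`` is the radius
    vector of patch p, ``tensor[p, :, 1]`` the center vector.
    """

    tensor: np.ndarray
    patch_size: int
    graph_type: str
    source_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.tensor.shape[0]

    @property
    def nodes_per_patch(self) -> int:
        return self.tensor.shape[1]

    @property
    def radii(self) -> np.ndarray:
        return self.tensor[:, :, 0]

    @property
    def centers(self) -> np.ndarray:
        return self.tensor[:, :, 1]


def extract(
    img: np.ndarray,
    patch_size: int,
    graph_type: str = "grid2d",
    knn_k: int | None = None,
    grayscale: bool = True,
) -> GCFeatures:
    """End-to-end GCFE: raw image -> P x N x 2 Gershgorin features.

    Pipeline: grayscale (if requested and needed) -> divide by 255 ->
    row-major partition into ``patch_size`` tiles -> per-patch graph of
    ``graph_type`` -> modified weighted Laplacian -> (radius, center)
    vectors. Deterministic for fixed inputs.
    """
    if graph_type not in GRAPH_TYPES:
        raise ValueError(f"unknown graph type {graph_type!r}")
    img = np.asarray(img)
    if grayscale and img.ndim == 3:
        img = pre.to_grayscale(img)
    norm = pre.normalize_minmax(img)
    patches = pre.partition(norm, patch_size)
    feats = []
    for patch in patches:
        L = mwl(build_graph(patch, graph_type, knn_k))
        feats.append(np.stack([gershgorin_radii(L), gershgorin_centers(L)], axis=1))
    return GCFeatures(
        tensor=np.stack(feats),
        patch_size=patch_size,
        graph_type=graph_type,
        source_shape=patches.source_shape,
    )


def layout_2d(f: GCFeatures) -> np.ndarray:
    """Two-row feature plane of shape ``(2, P*N, 1)``.

    Row 0 concatenates the radius vectors of all patches in patch order,
    row 1 the center vectors; the trailing axis is the single channel.
    """
    return np.stack([f.radii.ravel(), f.centers.ravel()])[:, :, np.newaxis]


def layout_1d(f: GCFeatures, order: str = "interleaved") -> np.ndarray:
    """Flat feature vector of length ``2*P*N``.

    ``interleaved`` (default) emits [R_1, C_1, R_2, C_2, ...] so each
    patch's two vectors stay adjacent; ``blocked`` emits all radii then
    all centers ([R_1..R_P, C_1..C_P]).
    """
    if order == "interleaved":
        return f.tensor.transpose(0, 2, 1).ravel()
    if order == "blocked":
        return np.concatenate([f.radii.ravel(), f.centers.ravel()])
    raise ValueError(f"unknown 1D order {order!r}")
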