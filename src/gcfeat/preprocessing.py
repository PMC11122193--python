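"""Image loading, normalization, grayscale conversion and patch partitioning.

Images enter the pipeline as 8-bit rasters (``M`` rows x ``N`` columns,
optionally 3 RGB channels). They are scaled to ``[0, 1]`` by fixed-range
division by 255 and partitioned into non-overlapping square patches whose
side must divide both image dimensions. Patch order and pixel-to-node order
are row-major throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PatchSet",
    "InvalidImageError",
    "InvalidPatchSizeError",
    "load_image",
    "normalize_minmax",
    "to_grayscale",
    "partition",
    "stitch",
    "valid_patch_sizes",
]

# Rec. 601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class InvalidImageError(ValueError):
    """Raised when pixel values or channel layout are unsupported."""


class InvalidPatchSizeError(ValueError):
    """Raised when the patch size does not divide the image dimensions."""


@dataclass(frozen=True)
class PatchSet:
    """Ordered row-major collection of p x p patches from one image.

    Attributes
    ----------
    patches : np.ndarray
        Array of shape ``(P, p, p)`` with values in ``[0, 1]``.
    patch_size : int
        Side length ``p`` of each square patch.
    source_shape : tuple[int, int]
        ``(M, N)`` of the source image.
    """

    patches: np.ndarray
    patch_size: int
    source_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    def __len__(self) -> int:
        return self.n_patches

    def __iter__(self):
        return iter(self.patches)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/BMP raster or ``.npy`` array as an 8-bit image."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    _check_raw(arr)
    return arr


def _check_raw(img: np.ndarray) -> None:
    if img.ndim not in (2, 3):
        raise InvalidImageError(f"expected 2D or 3D image, got ndim={img.ndim}")
    if img.ndim == 3 and img.shape[2] not in (1, 3):
        raise InvalidImageError(
            f"unsupported channel count {img.shape[2]}; expected 1 or 3"
        )
    if img.size == 0:
        raise InvalidImageError("empty image")
    if img.min() < 0 or img.max() > 255:
        raise InvalidImageError(
            f"pixel values outside [0, 255]: range [{img.min()}, {img.max()}]"
        )


def normalize_minmax(img: np.ndarray) -> np.ndarray:
    """Scale 8-bit intensities to ``[0, 1]`` by dividing by 255.

    Fixed-range scaling keeps identical patches from different images
    comparable; a per-image min/max would not.
    """
    img = np.asarray(img)
    _check_raw(img)
    return img.astype(np.float64) / 255.0


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel image to luminance (Rec. 601), rounded to int.

    Single-channel input is returned unchanged (a trailing singleton
    channel axis is squeezed away).
    """
    img = np.asarray(img)
    _check_raw(img)
    if img.ndim == 2:
        return img
    if img.shape[2] == 1:
        return img[:, :, 0]
    gray = np.rint(img.astype(np.float64) @ _LUMA)
    return gray.astype(img.dtype if np.issubdtype(img.dtype, np.integer) else np.int64)


def valid_patch_sizes(M: int, N: int) -> list[int]:
    """All p >= 1 that divide both image dimensions evenly."""
    return [p for p in range(1, min(M, N) + 1) if M % p == 0 and N % p == 0]


def partition(img: np.ndarray, p: int) -> PatchSet:
    """Split a normalized M x N image into (M/p)(N/p) tiles of size p x p.

    Tiles are ordered row-major over the patch grid; stitching them back
    with :func:`stitch` reproduces the input exactly.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise InvalidImageError("partition expects a single-channel 2D image")
    M, N = img.shape
    if p < 1 or M % p or N % p:
        raise InvalidPatchSizeError(
            f"patch size {p} does not divide {M}x{N}; "
            f"valid sizes: {valid_patch_sizes(M, N)}"
        )
    tiles = (
        img.reshape(M // p, p, N // p, p)
        .swapaxes(1, 2)
        .reshape(-1, p, p)
    )
    return PatchSet(patches=tiles, patch_size=p, source_shape=(M, N))


def stitch(ps: PatchSet) -> np.ndarray:
    """Inverse of :func:`partition`: reassemble the full image."""
    M, N = ps.source_shape
    p = ps.patch_size
    return (
        ps.patches.reshape(M // p, N // p, p, p)
        .swapaxes(1, 2)
        .reshape(M, N)
    )
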