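"""Image enhancement and content-aware reduction.

Two stages run before wavelet decomposition:

1. **CLAHE** — contrast-limited adaptive histogram equalization, spreading
   the low-contrast parenchymal histogram tile by tile with a clip limit so
   noise is not amplified unboundedly.
2. **Seam carving** — content-aware shrinking that repeatedly deletes the
   8-connected pixel path (seam) of minimal cumulative gradient energy,
   so low-information pixels are removed while structures survive.

The energy of a pixel is ``|dImg/dx| + |dImg/dy|``; the per-image total
energy is the sum of the map. Gradients are central differences on a
replicate-padded image, so the map is defined everywhere including borders.
Seam search is the classic dynamic-programming minimal-path recurrence with
steps {-1, 0, +1}; ties break toward the smallest index, which makes every
result deterministic. No randomness exists anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage import exposure

from .image_core import GrayImage

__all__ = [
    "ClaheParams",
    "EnergyMap",
    "Seam",
    "SeamKind",
    "apply_clahe",
    "compute_energy",
    "total_energy",
    "find_min_seam",
    "remove_seam",
    "carve",
]


class SeamKind(str, Enum):
    VERTICAL = "vertical"  # one column index per row; removal shrinks width
    HORIZONTAL = "horizontal"  # one row index per column; removal shrinks height


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE knobs: normalized clip limit and the tile grid.

    ``clip_limit`` is the fraction of a tile's histogram mass at which bins
    are clipped (0.01 is a conservative common default). ``tile_grid`` is
    (rows, cols) of contextual tiles.
    """

    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if any(t < 1 for t in self.tile_grid):
            raise ValueError("tile_grid entries must be >= 1")


@dataclass(frozen=True)
class EnergyMap:
    """Non-negative gradient-magnitude field, same shape as its source."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("EnergyMap must be 2D")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("EnergyMap entries must be finite and >= 0")
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class Seam:
    kind: SeamKind
    indices: np.ndarray  # length = height (vertical) or width (horizontal)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("seam indices must be 1D")
        if len(idx) > 1 and np.abs(np.diff(idx)).max() > 1:
            raise ValueError("seam violates 8-connectivity")
        object.__setattr__(self, "indices", idx)


def apply_clahe(img: GrayImage, params: ClaheParams | None = None) -> GrayImage:
    """Contrast-limited adaptive histogram equalization on [0,1] intensities."""
    if params is None:
        params = ClaheParams()
    rows, cols = params.tile_grid
    kernel = (max(1, img.height // rows), max(1, img.width // cols))
    if rows > img.height or cols > img.width:
        raise ValueError(
            f"tile grid {params.tile_grid} exceeds image shape {img.shape}"
        )
    px = img.pixels
    if px.max() == px.min():
        return GrayImage(px.copy())  # constant image: nothing to equalize
    out = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=params.clip_limit)
    return GrayImage(np.clip(out, 0.0, 1.0))


def compute_energy(img: GrayImage) -> EnergyMap:
    """Energy map |dI/dx| + |dI/dy| via central differences.

    The image is replicate-padded by one pixel so the central difference is
    defined at borders as well; a constant image therefore has identically
    zero energy.
    """
    if img.height < 2 or img.width < 2:
        raise ValueError("energy needs an image of at least 2x2")
    padded = np.pad(img.pixels, 1, mode="edge")
    dx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    dy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    return EnergyMap(np.abs(dx) + np.abs(dy))


def total_energy(img: GrayImage) -> float:
    """Scalar total gradient energy of an image (sum of its energy map)."""
    return compute_energy(img).total


def find_min_seam(E: EnergyMap, kind: SeamKind = SeamKind.VERTICAL) -> Seam:
    """Minimal-cumulative-energy 8-connected seam by dynamic programming.

    Among all minimal seams the smallest starting index wins, then the
    smallest index at each subsequent step (argmin returns the first
    occurrence, and candidate neighbors are scanned left/up first).
    """
    values = E.values
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("seam search needs at least a 2x2 energy map")
    if kind == SeamKind.HORIZONTAL:
        inner = find_min_seam(EnergyMap(values.T), SeamKind.VERTICAL)
        return Seam(SeamKind.HORIZONTAL, inner.indices)

    h, w = values.shape
    # M[i, j] = min energy of a seam from row i to the bottom passing (i, j),
    # accumulated bottom-up so the top-down walk can be greedy.
    M = values.copy()
    for i in range(h - 2, -1, -1):
        below = M[i + 1]
        shifted = np.full((3, w), np.inf)
        shifted[0, 1:] = below[:-1]  # step to j-1
        shifted[1] = below  # step to j
        shifted[2, :-1] = below[1:]  # step to j+1
        M[i] += shifted.min(axis=0)

    indices = np.empty(h, dtype=int)
    j = int(np.argmin(M[0]))
    indices[0] = j
    for i in range(1, h):
        lo, hi = max(0, j - 1), min(w, j + 2)
        j = lo + int(np.argmin(M[i, lo:hi]))
        indices[i] = j
    return Seam(SeamKind.VERTICAL, indices)


def seam_energy(E: EnergyMap, seam: Seam) -> float:
    """Total energy along a seam's path."""
    v = E.values if seam.kind == SeamKind.VERTICAL else E.values.T
    return float(v[np.arange(len(seam.indices)), seam.indices].sum())


def remove_seam(img: GrayImage, seam: Seam) -> GrayImage:
    """Delete one pixel per row (vertical) or per column (horizontal)."""
    px = img.pixels
    if seam.kind == SeamKind.HORIZONTAL:
        inner = remove_seam(GrayImage(px.T), Seam(SeamKind.VERTICAL, seam.indices))
        return GrayImage(inner.pixels.T)
    h, w = px.shape
    if len(seam.indices) != h or seam.indices.max() >= w or seam.indices.min() < 0:
        raise ValueError(f"seam of length {len(seam.indices)} invalid for image {px.shape}")
    keep = np.ones((h, w), dtype=bool)
    keep[np.arange(h), seam.indices] = False
    return GrayImage(px[keep].reshape(h, w - 1))


def carve(img: GrayImage, n_vertical: int = 0, n_horizontal: int = 0) -> GrayImage:
    """Remove seams iteratively, recomputing the energy after each removal.

    Vertical seams are removed first (shrinking width), then horizontal
    (shrinking height); the fixed order keeps the operation reproducible.
    """
    if n_vertical < 0 or n_horizontal < 0:
        raise ValueError("seam counts must be >= 0")
    if n_vertical >= img.width - 1 or n_horizontal >= img.height - 1:
        raise ValueError(
            f"cannot carve {n_vertical}x{n_horizontal} seams from image {img.shape}"
        )
    out = img
    for _ in range(n_vertical):
        out = remove_seam(out, find_min_seam(compute_energy(out), SeamKind.VERTICAL))
    for _ in range(n_horizontal):
        out = remove_seam(out, find_min_seam(compute_energy(out), SeamKind.HORIZONTAL))
    return out
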