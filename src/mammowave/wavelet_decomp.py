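"""Discrete 2D Haar wavelet analysis and synthesis.

One decomposition level splits an image into four subbands via the
separable orthonormal 2-tap Haar filter bank (scaling (1, 1)/sqrt(2),
wavelet (1, -1)/sqrt(2)):

* ``LL`` — approximation (low pass), the band fed to the wCNN
* ``LH`` — horizontal detail (wavelet along rows)
* ``HL`` — vertical detail (wavelet along columns)
* ``HH`` — diagonal detail

With the orthonormal normalization the transform conserves energy
(Parseval) and is exactly invertible. Odd dimensions are replicate-padded
to even on the right/bottom; the padding is recorded per level and stripped
on synthesis, so the round-trip is exact for any shape.

The multilevel (Mallat) pyramid re-decomposes only the LL band; the full
packet tree that recurses on all four children is available through
:func:`wavedec2_packet` but is not part of the default pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_core import GrayImage, normalize

__all__ = [
    "SubbandSet",
    "DecompPyramid",
    "dwt2_haar",
    "idwt2_haar",
    "wavedec2",
    "waverec2",
    "wavedec2_packet",
    "max_level",
    "extract_ll",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class SubbandSet:
    """The four subbands of one decomposition level plus padding bookkeeping."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    pad_info: tuple[bool, bool] = (False, False)  # (rows padded, cols padded)

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.LL, self.LH, self.HL, self.HH)}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")

    @property
    def bands(self) -> dict[str, np.ndarray]:
        return {"LL": self.LL, "LH": self.LH, "HL": self.HL, "HH": self.HH}


@dataclass(frozen=True)
class DecompPyramid:
    """Mallat pyramid: level k+1 decomposes level k's LL."""

    levels: tuple[SubbandSet, ...]

    @property
    def depth(self) -> int:
        return len(self.levels)


def _split_1d(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Orthonormal Haar analysis along one axis; replicate-pad odd lengths."""
    padded = x.shape[axis] % 2 == 1
    if padded:
        pad = [(0, 0), (0, 0)]
        pad[axis] = (0, 1)
        x = np.pad(x, pad, mode="edge")
    even = np.take(x, np.arange(0, x.shape[axis], 2), axis=axis)
    odd = np.take(x, np.arange(1, x.shape[axis], 2), axis=axis)
    return (even + odd) * _INV_SQRT2, (even - odd) * _INV_SQRT2, padded


def dwt2_haar(img: np.ndarray | GrayImage) -> SubbandSet:
    """One-level separable 2D Haar split into LL/LH/HL/HH."""
    x = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"dwt2_haar needs a 2D image of at least 2x2, got {x.shape}")
    lo_r, hi_r, cols_padded = _split_1d(x, axis=1)  # filter along rows (x)
    LL, HL_part = _split_1d(lo_r, axis=0)[:2]
    LH_part, HH_part = _split_1d(hi_r, axis=0)[:2]
    rows_padded = x.shape[0] % 2 == 1
    return SubbandSet(
        LL=LL, LH=LH_part, HL=HL_part, HH=HH_part, pad_info=(rows_padded, cols_padded)
    )


def _merge_1d(lo: np.ndarray, hi: np.ndarray, axis: int, padded: bool) -> np.ndarray:
    even = (lo + hi) * _INV_SQRT2
    odd = (lo - hi) * _INV_SQRT2
    n = lo.shape[axis] * 2
    shape = list(lo.shape)
    shape[axis] = n
    out = np.empty(shape, dtype=float)
    idx_even = [slice(None), slice(None)]
    idx_odd = [slice(None), slice(None)]
    idx_even[axis] = slice(0, n, 2)
    idx_odd[axis] = slice(1, n, 2)
    out[tuple(idx_even)] = even
    out[tuple(idx_odd)] = odd
    if padded:
        trim = [slice(None), slice(None)]
        trim[axis] = slice(0, n - 1)
        out = out[tuple(trim)]
    return out


def idwt2_haar(bands: SubbandSet) -> np.ndarray:
    """Exact inverse of :func:`dwt2_haar`, stripping any recorded padding."""
    rows_padded, cols_padded = bands.pad_info
    lo_r = _merge_1d(bands.LL, bands.HL, axis=0, padded=rows_padded)
    hi_r = _merge_1d(bands.LH, bands.HH, axis=0, padded=rows_padded)
    return _merge_1d(lo_r, hi_r, axis=1, padded=cols_padded)


def max_level(shape: tuple[int, int]) -> int:
    """Deepest usable level: floor(log2(min dimension)), by integer halving."""
    m = min(shape)
    if m < 2:
        raise ValueError(f"dimensions must be >= 2, got {shape}")
    level = 0
    while m >= 2:
        m //= 2
        level += 1
    return level


def wavedec2(img: np.ndarray | GrayImage, depth: int) -> DecompPyramid:
    """Multilevel Mallat decomposition: re-split the LL band ``depth`` times."""
    x = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    top = max_level(x.shape)
    if not 1 <= depth <= top:
        raise ValueError(f"depth {depth} outside [1, {top}] for shape {x.shape}")
    levels = []
    current = x
    for _ in range(depth):
        bands = dwt2_haar(current)
        levels.append(bands)
        current = bands.LL
    return DecompPyramid(tuple(levels))


def waverec2(pyr: DecompPyramid) -> np.ndarray:
    """Invert a Mallat pyramid back to the original image."""
    current = pyr.levels[-1].LL
    for bands in reversed(pyr.levels):
        bands = SubbandSet(current, bands.LH, bands.HL, bands.HH, bands.pad_info)
        current = idwt2_haar(bands)
    return current


def wavedec2_packet(img: np.ndarray | GrayImage, depth: int) -> dict:
    """Full wavelet packet tree: recurse on all four children.

    Returns a nested dict keyed by band name; leaves are arrays at the
    requested depth.
    """
    x = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    bands = dwt2_haar(x)
    if depth == 1 or min(bands.LL.shape) < 2:
        return bands.bands
    return {k: wavedec2_packet(v, depth - 1) for k, v in bands.bands.items()}


def extract_ll(pyr: DecompPyramid) -> GrayImage:
    """Deepest LL band, re-normalized to [0,1] for network consumption."""
    if pyr.depth < 1:
        raise ValueError("empty pyramid")
    return normalize(pyr.levels[-1].LL)
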