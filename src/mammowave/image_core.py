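"""Canonical grayscale image type and I/O.

Every stage of the pipeline exchanges :class:`GrayImage` — a single-channel
float field normalized to [0, 1]. Quantization to 8 bits happens only at the
PNG boundary; NPY round-trips are lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "LabeledSample",
    "SampleSource",
    "load_image",
    "save_image",
    "normalize",
]

# ITU-R 601 luma weights for deterministic color -> luminance collapse.
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageLoadError(RuntimeError):
    """Raised when a file exists but cannot be decoded as an image."""


@dataclass(frozen=True)
class GrayImage:
    """2D intensity field with values in [0, 1].

    Parameters
    ----------
    pixels
        Float array of shape ``(height, width)``. Validated on construction:
        must be 2D, finite, and within [0, 1].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2D array, got ndim={px.ndim}")
        if px.size == 0:
            raise ValueError("GrayImage requires at least one pixel")
        if not np.all(np.isfinite(px)):
            raise ValueError("GrayImage pixels must be finite")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ValueError(
                f"GrayImage pixels must lie in [0,1], got range "
                f"[{px.min():.4g}, {px.max():.4g}]"
            )
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


class SampleSource(str, Enum):
    REAL = "real"
    SYNTHETIC = "synthetic"
    GAN = "gan"


@dataclass(frozen=True)
class LabeledSample:
    """A labeled image with provenance (real / synthetic / gan)."""

    image: GrayImage
    label: str
    source: SampleSource = SampleSource.SYNTHETIC
    meta: dict = field(default_factory=dict, compare=False)


def normalize(raw: np.ndarray) -> GrayImage:
    """Affine-rescale an arbitrary finite 2D field to [0, 1].

    min maps to 0 and max to 1. A constant field maps to all zeros — a
    constant image carries no contrast information, so zero is the declared
    convention.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("normalize expects a non-empty 2D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("normalize requires finite values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return GrayImage(np.zeros_like(arr))
    return GrayImage((arr - lo) / (hi - lo))


def load_image(path: str | os.PathLike) -> GrayImage:
    """Load a PNG (or any Pillow-readable raster) or .npy array as GrayImage.

    Multi-channel input collapses to luminance with ITU-R 601 weights.
    8-bit integer data is scaled by 1/255; float NPY data must already be
    within [0, 1].
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image file not found: {p}")
    if p.suffix.lower() == ".npy":
        arr = np.load(p)
        if arr.ndim == 3:
            arr = arr @ _LUMA
        if arr.size == 0:
            raise ImageLoadError(f"empty array in {p}")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / 255.0
        return GrayImage(np.asarray(arr, dtype=float))
    try:
        with Image.open(p) as im:
            arr = np.asarray(im, dtype=float)
    except Exception as exc:  # Pillow raises various decode errors
        raise ImageLoadError(f"cannot decode {p}: {exc}") from exc
    if arr.size == 0:
        raise ImageLoadError(f"zero-sized image in {p}")
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return GrayImage(arr / 255.0)


def save_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write a GrayImage to 8-bit PNG or lossless .npy.

    PNG quantizes to 256 levels; round-trip error is at most 1/255 per pixel.
    """
    p = Path(path)
    if not p.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {p.parent}")
    if p.suffix.lower() == ".npy":
        np.save(p, img.pixels)
        return
    q = np.round(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(q, mode="L").save(p, format="PNG")
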