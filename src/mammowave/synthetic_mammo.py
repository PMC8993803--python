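"""Seeded generator of synthetic mammogram-like labeled images.

The generator emulates the gross appearance of screening-mammogram regions
of interest so every downstream stage is testable without clinical data:

* ``N``    — smooth low-contrast textured background only
* ``BM``   — benign mass: one or two moderate bright Gaussian blobs
* ``M``    — malignant mass: brighter / larger blobs than BM
* ``BC``   — benign calcification: a loose cluster of 1–3 px bright speckles
* ``CALC`` — calcification: a denser speckle cluster
* ``AD``   — architectural distortion: radial bright line segments
             converging on a focus
* ``ASYM`` — asymmetry: a monotone lateral intensity ramp over the background

The background is a sum of 2–4 low-frequency cosine gratings plus Gaussian
pixel noise, mimicking the low-contrast parenchymal texture that motivates
contrast enhancement. Identical :class:`SyntheticSpec` (including seed)
yields a bit-identical dataset.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

from .image_core import GrayImage, LabeledSample, SampleSource, save_image

__all__ = [
    "CLASSES_FIVE",
    "CLASSES_SEVEN",
    "SyntheticSpec",
    "LabeledDataset",
    "generate_sample",
    "generate_dataset",
    "split_dataset",
    "dump_dataset",
]

#: The five-class label set (normal, benign calcification, benign mass,
#: calcification, mass); seven-class mode adds architectural distortion
#: and asymmetry.
CLASSES_FIVE = ("N", "BC", "BM", "CALC", "M")
CLASSES_SEVEN = CLASSES_FIVE + ("AD", "ASYM")


class Split(str, Enum):
    TRAIN = "train"
    VAL = "val"
    TEST = "test"


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic dataset; a pure function of itself.

    ``lesion_intensity`` is the additive peak amplitude of class structures
    above the background (background occupies roughly [0.25, 0.55] before
    noise, so the default 0.45 keeps lesions clearly but not trivially
    brighter). ``noise_sd`` is the per-pixel Gaussian noise sigma.
    """

    image_size: int = 299
    class_counts: dict[str, int] = field(default_factory=lambda: {c: 10 for c in CLASSES_FIVE})
    seed: int = 0
    noise_sd: float = 0.02
    lesion_intensity: float = 0.45
    lesion_radius_px: int = 6

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.lesion_intensity <= 1):
            raise ValueError("lesion_intensity must be in (0, 1]")
        if self.lesion_radius_px < 1:
            raise ValueError("lesion_radius_px must be >= 1")


@dataclass(frozen=True)
class LabeledDataset:
    samples: tuple[LabeledSample, ...]
    class_set: tuple[str, ...]
    split: Split = Split.TRAIN

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.label not in self.class_set:
                raise ValueError(f"label {s.label!r} not in class set {self.class_set}")

    def __len__(self) -> int:
        return len(self.samples)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.class_set}
        for s in self.samples:
            out[s.label] += 1
        return out


def _derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary parts (below 2**31)."""
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _background(size: int, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Smooth low-contrast field: 2-4 low-frequency cosine gratings + noise."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    n_waves = int(rng.integers(2, 5))
    bg = np.full((size, size), 0.4)
    for _ in range(n_waves):
        fx, fy = rng.uniform(0.5, 3.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.02, 0.07)
        bg += amp * np.cos(2 * np.pi * (fx * xx + fy * yy) + phase)
    if noise_sd > 0:
        bg += rng.normal(0.0, noise_sd, size=(size, size))
    return bg


def _gaussian_blob(size: int, cy: float, cx: float, radius: float, amp: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return amp * np.exp(-r2 / (2.0 * radius**2))


def _add_masses(img, rng, spec: SyntheticSpec, malignant: bool) -> None:
    n = int(rng.integers(1, 3))
    scale = 1.0 if malignant else 0.55
    rad_scale = 1.4 if malignant else 1.0
    size = spec.image_size
    for _ in range(n):
        cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
        radius = spec.lesion_radius_px * rad_scale * rng.uniform(0.8, 1.3)
        img += _gaussian_blob(size, cy, cx, radius, spec.lesion_intensity * scale)


def _add_speckles(img, rng, spec: SyntheticSpec, dense: bool) -> None:
    size = spec.image_size
    cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
    n = int(rng.integers(12, 25)) if dense else int(rng.integers(4, 9))
    spread = 4.0 * spec.lesion_radius_px
    for _ in range(n):
        y = int(np.clip(round(cy + rng.normal(0, spread)), 1, size - 2))
        x = int(np.clip(round(cx + rng.normal(0, spread)), 1, size - 2))
        half = int(rng.integers(0, 2))  # speckle side 1 or 3 px
        img[y - half : y + half + 1, x - half : x + half + 1] += spec.lesion_intensity * rng.uniform(0.7, 1.0)


def _add_radial_lines(img, rng, spec: SyntheticSpec) -> None:
    size = spec.image_size
    cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
    n_rays = int(rng.integers(6, 12))
    length = 6.0 * spec.lesion_radius_px
    for _ in range(n_rays):
        theta = rng.uniform(0, 2 * np.pi)
        t = np.linspace(2.0, length, int(2 * length))
        ys = np.clip(np.round(cy + t * np.sin(theta)).astype(int), 0, size - 1)
        xs = np.clip(np.round(cx + t * np.cos(theta)).astype(int), 0, size - 1)
        img[ys, xs] += spec.lesion_intensity * 0.6
    img[int(cy), int(cx)] += spec.lesion_intensity * 0.3


def _add_lateral_ramp(img, rng, spec: SyntheticSpec) -> None:
    size = spec.image_size
    direction = 1 if rng.random() < 0.5 else -1
    ramp = np.linspace(0.0, spec.lesion_intensity * 0.6, size)[None, :]
    img += ramp if direction > 0 else ramp[:, ::-1]


_STRUCTURE = {
    "N": lambda img, rng, spec: None,
    "BM": lambda img, rng, spec: _add_masses(img, rng, spec, malignant=False),
    "M": lambda img, rng, spec: _add_masses(img, rng, spec, malignant=True),
    "BC": lambda img, rng, spec: _add_speckles(img, rng, spec, dense=False),
    "CALC": lambda img, rng, spec: _add_speckles(img, rng, spec, dense=True),
    "AD": lambda img, rng, spec: _add_radial_lines(img, rng, spec),
    "ASYM": lambda img, rng, spec: _add_lateral_ramp(img, rng, spec),
}


def generate_sample(
    label: str,
    size: int | None = None,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> LabeledSample:
    """Generate one labeled synthetic image.

    The image is the class structure added on top of the textured
    background, clipped to [0, 1]. Deterministic in ``(label, size, seed,
    spec)``.
    """
    if spec is None:
        spec = SyntheticSpec()
    if size is not None and size != spec.image_size:
        spec = replace(spec, image_size=size)
    if label not in _STRUCTURE:
        raise ValueError(f"unknown class label {label!r}")
    rng = np.random.default_rng(_derive_seed("sample", label, spec.image_size, seed))
    img = _background(spec.image_size, rng, spec.noise_sd)
    _STRUCTURE[label](img, rng, spec)
    return LabeledSample(
        image=GrayImage(np.clip(img, 0.0, 1.0)),
        label=label,
        source=SampleSource.SYNTHETIC,
        meta={"seed": seed},
    )


def generate_dataset(spec: SyntheticSpec, class_set: tuple[str, ...] | None = None) -> LabeledDataset:
    """Generate a dataset with exactly ``spec.class_counts`` per class.

    Each sample gets its own sub-seed derived from ``(spec.seed, class,
    index)``, so generation is order-independent and reproducible; the final
    ordering is a deterministic shuffle keyed on ``spec.seed``.
    """
    if not spec.class_counts:
        raise ValueError("class_counts must be non-empty")
    if class_set is None:
        class_set = tuple(spec.class_counts.keys())
    samples: list[LabeledSample] = []
    for label in class_set:
        for idx in range(spec.class_counts.get(label, 0)):
            samples.append(generate_sample(label, seed=_derive_seed(spec.seed, label, idx), spec=spec))
    order = np.random.default_rng(_derive_seed("shuffle", spec.seed)).permutation(len(samples))
    return LabeledDataset(tuple(samples[i] for i in order), class_set=class_set)


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified, seeded train/val/test partition.

    Within each class, samples are shuffled with the seed and dealt into
    splits by cumulative fraction; the three outputs are disjoint and
    exhaustive.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    rng = np.random.default_rng(_derive_seed("split", seed))
    buckets: dict[Split, list[LabeledSample]] = {s: [] for s in Split}
    for label in ds.class_set:
        members = [s for s in ds.samples if s.label == label]
        members = [members[i] for i in rng.permutation(len(members))]
        n = len(members)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        buckets[Split.TRAIN] += members[:n_train]
        buckets[Split.VAL] += members[n_train : n_train + n_val]
        buckets[Split.TEST] += members[n_train + n_val :]
    return tuple(
        LabeledDataset(tuple(buckets[s]), class_set=ds.class_set, split=s) for s in Split
    )


def dump_dataset(ds: LabeledDataset, out_dir: str | Path) -> Path:
    """Write PNGs as ``<split>/<label>/<index>.png`` plus a CSV manifest."""
    out = Path(out_dir)
    manifest = out / "manifest.csv"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[str, int] = {}
    for s in ds.samples:
        idx = counters.get(s.label, 0)
        counters[s.label] = idx + 1
        rel = Path(ds.split.value) / s.label / f"{idx}.png"
        (out / rel).parent.mkdir(parents=True, exist_ok=True)
        save_image(s.image, out / rel)
        rows.append((str(rel), s.label, ds.split.value, s.source.value, s.meta.get("seed", "")))
    with open(manifest, "a" if manifest.exists() else "w", newline="") as fh:
        w = csv.writer(fh)
        if fh.tell() == 0:
            w.writerow(["path", "label", "split", "source", "seed"])
        w.writerows(rows)
    return manifest
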