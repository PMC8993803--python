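"""DCGAN-style generator/discriminator for augmenting scarce classes.

The generator maps a 100-dimensional Gaussian noise vector through a dense
projection to a 4x4 feature stack and then stride-2 fractionally strided
5x5 convolutions (batch norm + ReLU) up to the configured output size,
ending in a tanh layer without batch norm. The discriminator mirrors this
with stride-2 5x5 convolutions (batch norm + LeakyReLU), a flatten, and a
single sigmoid unit. All weights start from a normal(0, 0.02) initializer.

Training uses the standard non-saturating adversarial objective with Adam
(generator lr 1e-5, discriminator lr 1e-4, beta1 0.5, beta2 0.999, batch
32 by default). One GAN is trained per abnormality class; images cross the
module boundary in [0, 1] and live in [-1, 1] inside the GAN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .image_core import GrayImage, LabeledSample, SampleSource
from .synthetic_mammo import LabeledDataset

__all__ = [
    "GanSpec",
    "GanTrainConfig",
    "build_generator",
    "build_discriminator",
    "train_gan",
    "synthesize",
]


@dataclass(frozen=True)
class GanSpec:
    noise_dim: int = 100
    gen_filters: tuple[int, ...] = (1024, 512, 256, 128, 64, 32)
    disc_filters: tuple[int, ...] = (64, 128, 256, 512, 1024)
    kernel_size: int = 5
    output_size: int = 256
    output_channels: int = 1

    def __post_init__(self) -> None:
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")
        size, ups = 4, 0
        while size < self.output_size:
            size *= 2
            ups += 1
        if size != self.output_size:
            raise ValueError(f"output_size {self.output_size} not reachable from 4x4 by doubling")
        if ups > len(self.gen_filters):
            raise ValueError("not enough gen_filters for the requested output_size")

    @property
    def n_upsamples(self) -> int:
        return int(np.log2(self.output_size // 4))


@dataclass(frozen=True)
class GanTrainConfig:
    batch_size: int = 32
    gen_lr: float = 1e-5
    disc_lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    steps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gen_lr <= 0 or self.disc_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (real and fake)")


class Generator:
    def __init__(self, spec: GanSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        n_up = spec.n_upsamples
        self.proj = nn.Dense(spec.noise_dim, 4 * 4 * spec.gen_filters[0],
                             init="normal0.02", rng=rng)
        layers: list[nn.Layer] = [nn.BatchNorm2D(spec.gen_filters[0]), nn.ReLU()]
        in_ch = spec.gen_filters[0]
        for i in range(n_up - 1):
            out_ch = spec.gen_filters[i + 1]
            layers += [
                nn.ConvTranspose2D(in_ch, out_ch, k=spec.kernel_size, stride=2, rng=rng),
                nn.BatchNorm2D(out_ch),
                nn.ReLU(),
            ]
            in_ch = out_ch
        layers += [
            nn.ConvTranspose2D(in_ch, spec.output_channels, k=spec.kernel_size,
                               stride=2, rng=rng),
            nn.Tanh(),
        ]
        self.body = nn.Sequential(layers)

    def forward(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        if z.ndim != 2 or z.shape[1] != self.spec.noise_dim:
            raise ValueError(f"noise batch must be (n, {self.spec.noise_dim}), got {z.shape}")
        h = self.proj.forward(z, train=train)
        h = h.reshape(len(z), self.spec.gen_filters[0], 4, 4)
        return self.body.forward(h, train=train)

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.body.backward(grad)
        return self.proj.backward(g.reshape(len(g), -1))

    def parameters(self):
        return self.proj.parameters() + self.body.parameters()

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0


class Discriminator:
    def __init__(self, spec: GanSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        n_down = spec.n_upsamples
        layers: list[nn.Layer] = []
        in_ch = spec.output_channels
        for i in range(n_down):
            out_ch = spec.disc_filters[min(i, len(spec.disc_filters) - 1)]
            layers += [
                nn.Conv2D(in_ch, out_ch, k=spec.kernel_size, stride=2,
                          init="normal0.02", rng=rng),
                nn.BatchNorm2D(out_ch),
                nn.LeakyReLU(0.2),
            ]
            in_ch = out_ch
        layers += [nn.Flatten(), nn.Dense(4 * 4 * in_ch, 1, init="normal0.02", rng=rng),
                   nn.Sigmoid()]
        self.net = nn.Sequential(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[2] != self.spec.output_size or x.shape[3] != self.spec.output_size:
            raise ValueError(
                f"discriminator expects {self.spec.output_size}-sized images, got {x.shape}"
            )
        return self.net.forward(x, train=train)[:, 0]

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad[:, None])

    def parameters(self):
        return self.net.parameters()

    def zero_grad(self):
        self.net.zero_grad()


def build_generator(spec: GanSpec | None = None, seed: int = 0) -> Generator:
    return Generator(spec or GanSpec(), seed=seed)


def build_discriminator(spec: GanSpec | None = None, seed: int = 0) -> Discriminator:
    return Discriminator(spec or GanSpec(), seed=seed)


def _to_gan_range(px: np.ndarray) -> np.ndarray:
    return px * 2.0 - 1.0


def _from_gan_range(px: np.ndarray) -> np.ndarray:
    return np.clip((px + 1.0) / 2.0, 0.0, 1.0)


def train_gan(data: LabeledDataset, cfg: GanTrainConfig, spec: GanSpec,
              gen: Generator | None = None, disc: Discriminator | None = None):
    """Alternating adversarial training on a single-class dataset.

    Returns ``(generator, discriminator, traces)`` where ``traces`` is a
    dict of per-step generator/discriminator losses (all finite or the run
    aborts).
    """
    labels = {s.label for s in data.samples}
    if len(labels) != 1:
        raise ValueError(f"train_gan expects a single-class dataset, got labels {labels}")
    if len(data) < cfg.batch_size:
        raise ValueError(f"need >= batch_size={cfg.batch_size} images, got {len(data)}")
    size = spec.output_size
    reals = np.stack([
        _resize_nearest(s.image.pixels, size) for s in data.samples
    ])[:, None, :, :]
    reals = _to_gan_range(reals)

    rng = np.random.default_rng(cfg.seed)
    gen = gen or Generator(spec, seed=int(rng.integers(2**31 - 1)))
    disc = disc or Discriminator(spec, seed=int(rng.integers(2**31 - 1)))
    opt_g = nn.Adam(gen.parameters(), lr=cfg.gen_lr, beta1=cfg.beta1, beta2=cfg.beta2)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.disc_lr, beta1=cfg.beta1, beta2=cfg.beta2)

    traces = {"disc_loss": [], "gen_loss": []}
    half = cfg.batch_size // 2
    for step in range(cfg.steps):
        # --- discriminator update: real batch toward 1, fake toward 0
        idx = rng.choice(len(reals), size=half, replace=len(reals) < half)
        z = rng.standard_normal((half, spec.noise_dim))
        fake = gen.forward(z, train=True)
        disc.zero_grad()
        p_real = disc.forward(reals[idx], train=True)
        loss_r, dp_r = nn.binary_cross_entropy(p_real, 1.0)
        disc.backward(dp_r)
        p_fake = disc.forward(fake, train=True)
        loss_f, dp_f = nn.binary_cross_entropy(p_fake, 0.0)
        disc.backward(dp_f)
        opt_d.step()
        d_loss = loss_r + loss_f

        # --- generator update: non-saturating, push D(fake) toward 1
        z = rng.standard_normal((cfg.batch_size, spec.noise_dim))
        gen.zero_grad()
        disc.zero_grad()
        fake = gen.forward(z, train=True)
        p = disc.forward(fake, train=True)
        g_loss, dp = nn.binary_cross_entropy(p, 1.0)
        dfake = disc.backward(dp)
        gen.backward(dfake)
        opt_g.step()

        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise FloatingPointError(
                f"non-finite GAN loss at step {step}: d={d_loss}, g={g_loss}"
            )
        traces["disc_loss"].append(float(d_loss))
        traces["gen_loss"].append(float(g_loss))
    return gen, disc, traces


def _resize_nearest(px: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor square resize (used only at the GAN boundary)."""
    h, w = px.shape
    if (h, w) == (size, size):
        return px
    rows = (np.arange(size) * h // size).clip(0, h - 1)
    cols = (np.arange(size) * w // size).clip(0, w - 1)
    return px[np.ix_(rows, cols)]


def synthesize(gen: Generator, n: int, label: str, seed: int = 0,
               working_size: int | None = None) -> list[LabeledSample]:
    """Draw ``n`` images from the generator, tagged with label and source=gan."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, gen.spec.noise_dim))
    imgs = _from_gan_range(gen.forward(z, train=False))[:, 0]
    out = []
    for i in range(n):
        px = imgs[i]
        if working_size is not None:
            px = _resize_nearest(px, working_size)
        out.append(LabeledSample(GrayImage(px), label=label, source=SampleSource.GAN,
                                 meta={"seed": seed, "index": i}))
    return out
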