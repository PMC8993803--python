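"""CNN and wCNN builders plus the training loop.

Both architectures share one topology — the default is six convolutional
blocks of three same-padded 3x3 convolutions each (L2 factor 0.0002 on
every kernel) followed by 2x2 max pooling, then flatten, dropout 0.5, and
a dense softmax head. The only difference between the two is the
elementwise activation after every convolution: ReLU for the basic CNN,
the wavelet function cos(beta*x)*exp(-x^2/2) for the wCNN. The activation
carries no trainable parameters, so the two models always have identical
parameter counts.

The default filter schedule doubles per block as powers of two,
[32, 64, 128, 256, 512, 512] (the cap repeats for the sixth block). Default
input is a 299x299 single-channel image; when the pipeline feeds the
deepest wavelet approximation band instead, the input size is set from the
band's actual shape rather than upsampling back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .image_core import GrayImage
from .synthetic_mammo import LabeledDataset
from .wavelet_activation import ActivationParams, WaveletActivation

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainHistory",
    "Model",
    "build_cnn",
    "build_wcnn",
    "train_model",
    "predict",
]


@dataclass(frozen=True)
class NetworkSpec:
    input_size: int = 299
    input_channels: int = 1
    n_blocks: int = 6
    convs_per_block: int = 3
    kernel_size: int = 3
    filters_per_block: tuple[int, ...] = (32, 64, 128, 256, 512, 512)
    activation: str = "relu"  # "relu" | "wavelet"
    activation_params: ActivationParams = field(default_factory=ActivationParams)
    l2_factor: float = 0.0002
    dropout_rate: float = 0.5
    n_classes: int = 5

    def __post_init__(self) -> None:
        if len(self.filters_per_block) != self.n_blocks:
            raise ValueError("filters_per_block length must equal n_blocks")
        if self.activation not in ("relu", "wavelet"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        size = self.input_size
        for _ in range(self.n_blocks):
            size //= 2
            if size < 1:
                raise ValueError(
                    f"input size {self.input_size} collapses below 1x1 after "
                    f"{self.n_blocks} pooling stages"
                )

    def final_spatial(self) -> int:
        size = self.input_size
        for _ in range(self.n_blocks):
            size //= 2
        return size


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float = 1e-5
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0
    validation: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": i + 1,
                "loss": self.loss[i],
                "accuracy": self.accuracy[i],
                "val_loss": self.val_loss[i] if self.val_loss else "",
                "val_accuracy": self.val_accuracy[i] if self.val_accuracy else "",
            }
            for i in range(len(self.loss))
        ]


class Model:
    """A built network: the layer stack plus its spec and class ordering."""

    def __init__(self, net: nn.Sequential, spec: NetworkSpec, class_set: tuple[str, ...]):
        self.net = net
        self.spec = spec
        self.class_set = class_set

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def conv_layers(self) -> list[nn.Conv2D]:
        return [l for l in self.net.layers if isinstance(l, nn.Conv2D)]


def _build(spec: NetworkSpec, seed: int, class_set: tuple[str, ...] | None) -> Model:
    rng = np.random.default_rng(seed)
    if class_set is None:
        class_set = tuple(str(i) for i in range(spec.n_classes))
    if len(class_set) != spec.n_classes:
        raise ValueError("class_set length must equal n_classes")

    def activation() -> nn.Layer:
        if spec.activation == "relu":
            return nn.ReLU()
        return WaveletActivation(spec.activation_params)

    init = "he" if spec.activation == "relu" else "wavelet"
    layers: list[nn.Layer] = []
    in_ch = spec.input_channels
    for filters in spec.filters_per_block:
        for _ in range(spec.convs_per_block):
            layers.append(
                nn.Conv2D(in_ch, filters, k=spec.kernel_size, l2=spec.l2_factor,
                          init=init, rng=rng)
            )
            layers.append(activation())
            in_ch = filters
        layers.append(nn.MaxPool2D())
    flat = spec.final_spatial() ** 2 * spec.filters_per_block[-1]
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(spec.dropout_rate, seed=int(rng.integers(2**31 - 1))))
    layers.append(nn.Dense(flat, spec.n_classes, init="glorot", rng=rng))
    layers.append(nn.Softmax())
    return Model(nn.Sequential(layers), spec, class_set)


def build_cnn(spec: NetworkSpec | None = None, seed: int = 0,
              class_set: tuple[str, ...] | None = None) -> Model:
    """Basic CNN: ReLU activations throughout."""
    spec = spec or NetworkSpec()
    if spec.activation != "relu":
        raise ValueError("build_cnn requires activation='relu'")
    return _build(spec, seed, class_set)


def build_wcnn(spec: NetworkSpec | None = None, seed: int = 0,
               class_set: tuple[str, ...] | None = None) -> Model:
    """wCNN: identical topology with the wavelet activation after each conv."""
    if spec is None:
        spec = NetworkSpec(activation="wavelet")
    if spec.activation != "wavelet":
        raise ValueError("build_wcnn requires activation='wavelet'")
    return _build(spec, seed, class_set)


def _as_batch(images, size: int) -> np.ndarray:
    arrs = []
    for im in images:
        px = im.pixels if isinstance(im, GrayImage) else np.asarray(im, dtype=float)
        if px.shape != (size, size):
            raise ValueError(f"image shape {px.shape} does not match model input {size}")
        arrs.append(px)
    return np.stack(arrs)[:, None, :, :]


def _dataset_arrays(ds: LabeledDataset, model: Model) -> tuple[np.ndarray, np.ndarray]:
    label_idx = {c: i for i, c in enumerate(model.class_set)}
    x = _as_batch([s.image for s in ds.samples], model.spec.input_size)
    y = np.array([label_idx[s.label] for s in ds.samples], dtype=int)
    return x, y


def _evaluate(model: Model, x: np.ndarray, y: np.ndarray, batch: int = 64):
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        probs = model.forward(x[i : i + batch], train=False)
        loss, _ = nn.cross_entropy(probs, y[i : i + batch])
        losses.append(loss * len(probs))
        correct += int((probs.argmax(axis=1) == y[i : i + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_model(model: Model, train: LabeledDataset, val: LabeledDataset | None,
                cfg: TrainConfig) -> TrainHistory:
    """Mini-batch training with categorical cross-entropy plus L2 penalty.

    Shuffling, and hence the whole run, is a pure function of ``cfg.seed``.
    Aborts with a diagnostic if the loss goes non-finite.
    """
    if len(train) == 0 or (cfg.validation and val is not None and len(val) == 0):
        raise ValueError("datasets must be non-empty")
    x_train, y_train = _dataset_arrays(train, model)
    x_val = y_val = None
    if cfg.validation and val is not None:
        x_val, y_val = _dataset_arrays(val, model)
    params = model.net.parameters()
    if cfg.optimizer == "adam":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    elif cfg.optimizer == "sgd":
        opt = nn.SGD(params, lr=cfg.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        ep_losses, ep_correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.net.zero_grad()
            probs = model.forward(xb, train=True)
            loss, dprobs = nn.cross_entropy(probs, yb)
            loss_total = loss + model.net.l2_penalty()
            if not np.isfinite(loss_total):
                raise FloatingPointError(
                    f"non-finite training loss {loss_total} at epoch {len(hist) + 1}"
                )
            model.net.backward(dprobs)
            opt.step()
            ep_losses.append(loss_total * len(xb))
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
        hist.loss.append(float(np.sum(ep_losses) / len(x_train)))
        hist.accuracy.append(ep_correct / len(x_train))
        if x_val is not None:
            vl, va = _evaluate(model, x_val, y_val)
            hist.val_loss.append(vl)
            hist.val_accuracy.append(va)
    return hist


def predict(model: Model, images) -> tuple[np.ndarray, list[str]]:
    """Class probabilities and argmax labels (smallest index wins ties)."""
    if isinstance(images, LabeledDataset):
        images = [s.image for s in images.samples]
    elif isinstance(images, GrayImage):
        images = [images]
    x = _as_batch(images, model.spec.input_size)
    probs = model.forward(x, train=False)
    labels = [model.class_set[i] for i in probs.argmax(axis=1)]
    return probs, labels
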