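"""Minimal NumPy neural-network engine used by the CNN/wCNN and the GAN.

Layers follow one contract: ``forward(x, train)`` caches what ``backward``
needs, ``backward(grad)`` accumulates parameter gradients and returns the
gradient with respect to the input, ``parameters()`` yields :class:`Param`
objects. Tensors are NCHW float64 throughout; every random draw (init,
dropout) flows through a seeded ``numpy.random.Generator``, so identical
seeds give bit-identical runs on one machine.

Every layer's backward pass is validated against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm2D",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Dropout",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Softmax",
    "Sequential",
    "cross_entropy",
    "binary_cross_entropy",
    "SGD",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient and optional L2 coefficient."""

    __slots__ = ("value", "grad", "l2", "name")

    def __init__(self, value: np.ndarray, l2: float = 0.0, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.l2 = l2
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []


# Gain restoring unit pre-activation variance under the wavelet activation
# psi(x) = cos(0.5 x) exp(-x^2/2): Var[psi(Z)] ~= 0.0918 for Z ~ N(0,1), so
# scaling Glorot weights by 1/sqrt(Var) ~= 3.30 keeps signal variance from
# collapsing layer to layer (the analogue of He's sqrt(2) gain for ReLU).
WAVELET_INIT_GAIN = 3.30


def _init_weight(shape, fan_in, scheme: str, rng: np.random.Generator) -> np.ndarray:
    if scheme == "he":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    if scheme in ("glorot", "wavelet"):
        fan_out = int(np.prod(shape)) // fan_in
        std = np.sqrt(2.0 / (fan_in + fan_out))
        if scheme == "wavelet":
            std *= WAVELET_INIT_GAIN
        return rng.normal(0.0, std, size=shape)
    if scheme == "normal0.02":  # DCGAN-style normal initializer
        return rng.normal(0.0, 0.02, size=shape)
    raise ValueError(f"unknown init scheme {scheme!r}")


def _same_pad(in_size: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-in_size // stride)  # ceil
    total = max((out - 1) * stride + k - in_size, 0)
    return total // 2, total - total // 2


class Conv2D(Layer):
    """2D convolution, 'same' zero-padding, arbitrary stride, im2col matmul."""

    def __init__(self, in_ch, out_ch, k=3, stride=1, l2=0.0, init="he",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = Param(_init_weight((out_ch, in_ch, k, k), in_ch * k * k, init, rng),
                       l2=l2, name="conv.W")
        self.b = Param(np.zeros(out_ch), name="conv.b")
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        pt, pb = _same_pad(h, self.k, self.stride)
        pl, pr = _same_pad(w, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (n,c,oh,ow,k,k)
        oh, ow = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, -1)
        w_mat = self.W.value.reshape(self.out_ch, -1)
        out = cols @ w_mat.T + self.b.value
        self._cache = (x.shape, (pt, pb, pl, pr), cols)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        (n, c, h, w), (pt, pb, pl, pr), cols = self._cache
        g = grad.transpose(0, 2, 3, 1)  # (n,oh,ow,out_ch)
        oh, ow = g.shape[1], g.shape[2]
        w_mat = self.W.value.reshape(self.out_ch, -1)
        self.W.grad += np.einsum("nhwo,nhwc->oc", g, cols).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=(0, 1, 2))
        dcols = (g @ w_mat).reshape(n, oh, ow, c, self.k, self.k)
        dxp = np.zeros((n, c, h + pt + pb, w + pl + pr))
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, pt : pt + h, pl : pl + w]

    def parameters(self):
        return [self.W, self.b]


class ConvTranspose2D(Layer):
    """Fractionally strided convolution: output spatial size = input * stride."""

    def __init__(self, in_ch, out_ch, k=5, stride=2, init="normal0.02",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = Param(_init_weight((in_ch, out_ch, k, k), in_ch * k * k, init, rng),
                       name="convT.W")
        self.b = Param(np.zeros(out_ch), name="convT.b")
        self._cache = None

    def _pads(self, h_in, w_in):
        h_out, w_out = h_in * self.stride, w_in * self.stride
        pt, pb = _same_pad(h_out, self.k, self.stride)
        pl, pr = _same_pad(w_out, self.k, self.stride)
        return h_out, w_out, pt, pb, pl, pr

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h_out, w_out, pt, pb, pl, pr = self._pads(h, w)
        s = self.stride
        yp = np.zeros((n, self.out_ch, h_out + pt + pb, w_out + pl + pr))
        for ki in range(self.k):
            for kj in range(self.k):
                contrib = np.einsum("nihw,io->nohw", x, self.W.value[:, :, ki, kj])
                yp[:, :, ki : ki + s * h : s, kj : kj + s * w : s] += contrib
        y = yp[:, :, pt : pt + h_out, pl : pl + w_out] + self.b.value[None, :, None, None]
        self._cache = (x, (pt, pb, pl, pr))
        return y

    def backward(self, grad):
        x, (pt, pb, pl, pr) = self._cache
        n, c, h, w = x.shape
        s = self.stride
        gp = np.pad(grad, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        dx = np.zeros_like(x)
        for ki in range(self.k):
            for kj in range(self.k):
                g_slice = gp[:, :, ki : ki + s * h : s, kj : kj + s * w : s]
                dx += np.einsum("nohw,io->nihw", g_slice, self.W.value[:, :, ki, kj])
                self.W.grad[:, :, ki, kj] += np.einsum("nihw,nohw->io", x, g_slice)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        return dx

    def parameters(self):
        return [self.W, self.b]


class BatchNorm2D(Layer):
    def __init__(self, ch, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(ch), name="bn.gamma")
        self.beta = Param(np.zeros(ch), name="bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, std, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g / std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std[None, :, None, None]
        return dx

    def parameters(self):
        return [self.gamma, self.beta]


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2, floor mode (odd trailing row/col dropped)."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"cannot pool spatial size {(h, w)} below 1")
        xc = x[:, :, : 2 * h2, : 2 * w2]
        r = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, grad):
        (n, c, h, w), idx = self._cache
        h2, w2 = h // 2, w // 2
        dr = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dr, idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, l2=0.0, init="he", rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_init_weight((n_in, n_out), n_in, init, rng), l2=l2, name="dense.W")
        self.b = Param(np.zeros(n_out), name="dense.b")

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Owns a seeded RNG stream."""

    def __init__(self, rate=0.5, seed=0):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Softmax(Layer):
    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=1, keepdims=True))


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def l2_penalty(self) -> float:
        return float(sum(p.l2 * np.sum(p.value**2) for p in self.parameters() if p.l2))

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps=1e-12):
    """Mean categorical cross-entropy on probabilities; returns (loss, dprobs)."""
    n = probs.shape[0]
    p = np.clip(probs, eps, 1.0)
    loss = -float(np.log(p[np.arange(n), y]).mean())
    dp = np.zeros_like(probs)
    dp[np.arange(n), y] = -1.0 / (p[np.arange(n), y] * n)
    return loss, dp


def binary_cross_entropy(p: np.ndarray, target: float | np.ndarray, eps=1e-7):
    """Mean BCE on probabilities in (0,1); returns (loss, dp)."""
    p = np.clip(p, eps, 1.0 - eps)
    t = np.broadcast_to(np.asarray(target, dtype=float), p.shape)
    loss = -float((t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
    dp = (-(t / p) + (1 - t) / (1 - p)) / p.size
    return loss, dp


class SGD:
    def __init__(self, params: list[Param], lr: float):
        self.params, self.lr = params, lr

    def step(self):
        for p in self.params:
            g = p.grad + 2.0 * p.l2 * p.value if p.l2 else p.grad
            p.value -= self.lr * g


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + 2.0 * p.l2 * p.value if p.l2 else p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
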