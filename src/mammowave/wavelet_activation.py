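"""The wavelet activation function psi(x) = cos(beta*x) * exp(-x^2/2).

A cosine under a Gaussian envelope (real Morlet-type form) used elementwise
in place of ReLU inside the convolutional layers of the wCNN. Unlike ReLU
it is bounded (|psi| <= exp(-x^2/2) <= 1), smooth everywhere, and decays to
zero away from the origin, so pre-activations far from zero are silenced
rather than passed through.

``beta`` controls the oscillation frequency under the envelope; it is a
hyperparameter (default 0.5), global to the network and never trained.

The analytic derivative used for backpropagation is

    dpsi/dx = -beta * sin(beta*x) * exp(-x^2/2) - x * cos(beta*x) * exp(-x^2/2)

validated against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ActivationParams", "psi", "psi_grad", "WaveletActivation", "as_activation_layer"]

# Beyond this |x| the Gaussian envelope exp(-x^2/2) < 1e-347: flush to zero
# rather than let subnormal noise through.
_FLUSH_ABOVE = 40.0


@dataclass(frozen=True)
class ActivationParams:
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("wavelet activation received non-finite input")


def psi(x, params: ActivationParams | None = None):
    """Elementwise cos(beta*x) * exp(-x^2/2); scalar in, scalar out."""
    if params is None:
        params = ActivationParams()
    arr = np.asarray(x, dtype=float)
    _check_finite(arr)
    out = np.where(
        np.abs(arr) > _FLUSH_ABOVE,
        0.0,
        np.cos(params.beta * arr) * np.exp(-0.5 * np.square(arr)),
    )
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def psi_grad(x, params: ActivationParams | None = None):
    """Analytic derivative of :func:`psi` with the same flush-to-zero policy."""
    if params is None:
        params = ActivationParams()
    arr = np.asarray(x, dtype=float)
    _check_finite(arr)
    b = params.beta
    env = np.exp(-0.5 * np.square(arr))
    out = np.where(
        np.abs(arr) > _FLUSH_ABOVE,
        0.0,
        -b * np.sin(b * arr) * env - arr * np.cos(b * arr) * env,
    )
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


class WaveletActivation:
    """Parameter-free activation layer: forward psi, backward chain rule.

    Conforms to the layer contract of :mod:`mammowave.nn` — ``forward``
    caches the input, ``backward`` multiplies the upstream gradient by the
    analytic derivative evaluated at that input.
    """

    def __init__(self, params: ActivationParams | None = None):
        self.params = params or ActivationParams()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return psi(x, self.params)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * psi_grad(self._x, self.params)

    def parameters(self):
        return []


def as_activation_layer(params: ActivationParams | None = None) -> WaveletActivation:
    """Factory matching the network builder's activation contract."""
    return WaveletActivation(params)
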