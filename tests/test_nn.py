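"""Gradient checks for every layer of the NumPy engine.

Each layer's backward pass is compared with central finite differences of
the scalar loss sum(forward(x) * R) for a fixed random projection R, both
with respect to the input and to every parameter.
"""

import numpy as np
import pytest

from mammowave import nn


def fd_input_grad(layer, x, R, h=1e-6, train=True):
    g = np.zeros_like(x)
    flat, gflat = x.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        up = np.sum(layer.forward(x, train=train) * R)
        flat[i] = orig - h
        down = np.sum(layer.forward(x, train=train) * R)
        flat[i] = orig
        gflat[i] = (up - down) / (2 * h)
    return g


def fd_param_grad(layer, param, x, R, h=1e-6, train=True):
    g = np.zeros_like(param.value)
    flat, gflat = param.value.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        up = np.sum(layer.forward(x, train=train) * R)
        flat[i] = orig - h
        down = np.sum(layer.forward(x, train=train) * R)
        flat[i] = orig
        gflat[i] = (up - down) / (2 * h)
    return g


def check_layer(layer, x, train=True, atol=1e-7):
    rng = np.random.default_rng(99)
    out = layer.forward(x, train=train)
    R = rng.normal(size=out.shape)
    for p in layer.parameters():
        p.grad[...] = 0.0
    analytic_dx = layer.backward(R)
    assert np.abs(analytic_dx - fd_input_grad(layer, x, R, train=train)).max() < atol
    for p in layer.parameters():
        assert np.abs(p.grad - fd_param_grad(layer, p, x, R, train=train)).max() < atol


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestConvolution:
    def test_conv_stride1_gradients(self, rng):
        layer = nn.Conv2D(2, 3, k=3, stride=1, rng=rng)
        check_layer(layer, rng.normal(size=(2, 2, 5, 5)))

    def test_conv_stride2_gradients(self, rng):
        layer = nn.Conv2D(2, 2, k=5, stride=2, rng=rng)
        check_layer(layer, rng.normal(size=(1, 2, 6, 6)))

    def test_same_padding_shape(self, rng):
        layer = nn.Conv2D(1, 4, k=3, stride=1, rng=rng)
        assert layer.forward(rng.normal(size=(1, 1, 7, 9))).shape == (1, 4, 7, 9)
        layer2 = nn.Conv2D(1, 4, k=5, stride=2, rng=rng)
        assert layer2.forward(rng.normal(size=(1, 1, 8, 8))).shape == (1, 4, 4, 4)

    def test_conv_transpose_gradients(self, rng):
        layer = nn.ConvTranspose2D(2, 2, k=5, stride=2, rng=rng)
        check_layer(layer, rng.normal(size=(1, 2, 3, 3)))

    def test_conv_transpose_doubles_spatial_size(self, rng):
        layer = nn.ConvTranspose2D(3, 1, k=5, stride=2, rng=rng)
        assert layer.forward(rng.normal(size=(2, 3, 4, 4))).shape == (2, 1, 8, 8)


class TestOtherLayers:
    def test_dense_gradients(self, rng):
        check_layer(nn.Dense(6, 4, rng=rng), rng.normal(size=(3, 6)))

    def test_batchnorm_train_gradients(self, rng):
        check_layer(nn.BatchNorm2D(3), rng.normal(size=(4, 3, 3, 3)), atol=1e-6)

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = nn.BatchNorm2D(2)
        x = rng.normal(size=(8, 2, 4, 4)) * 3 + 1
        bn.forward(x, train=True)
        out_eval = bn.forward(x, train=False)
        # eval output uses running stats, not the batch stats
        assert not np.allclose(out_eval.mean(axis=(0, 2, 3)), 0.0, atol=1e-3)

    def test_maxpool_gradients(self, rng):
        check_layer(nn.MaxPool2D(), rng.normal(size=(2, 2, 6, 6)))

    def test_maxpool_floor_mode(self, rng):
        out = nn.MaxPool2D().forward(rng.normal(size=(1, 1, 7, 5)))
        assert out.shape == (1, 1, 3, 2)

    def test_softmax_gradients(self, rng):
        check_layer(nn.Softmax(), rng.normal(size=(3, 5)))

    @pytest.mark.parametrize("act", [nn.ReLU, nn.Tanh, nn.Sigmoid,
                                     lambda: nn.LeakyReLU(0.2)])
    def test_activation_gradients(self, rng, act):
        # offset away from ReLU's kink at 0 so finite differences are valid
        x = rng.normal(size=(3, 4)) + 0.05 * np.sign(rng.normal(size=(3, 4)))
        x[np.abs(x) < 1e-3] = 0.1
        check_layer(act(), x)

    def test_dropout_eval_is_identity(self, rng):
        x = rng.normal(size=(4, 10))
        assert np.array_equal(nn.Dropout(0.5, seed=1).forward(x, train=False), x)

    def test_dropout_train_preserves_expectation(self):
        x = np.ones((200, 200))
        out = nn.Dropout(0.5, seed=1).forward(x, train=True)
        assert abs(out.mean() - 1.0) < 0.02


class TestLossesAndOptim:
    def test_cross_entropy_gradient(self, rng):
        probs = rng.dirichlet(np.ones(4), size=5)
        y = rng.integers(0, 4, size=5)
        loss, dp = nn.cross_entropy(probs, y)
        h = 1e-7
        for i, j in [(0, 0), (2, 3), (4, 1)]:
            pp = probs.copy()
            pp[i, j] += h
            up, _ = nn.cross_entropy(pp, y)
            pp[i, j] -= 2 * h
            down, _ = nn.cross_entropy(pp, y)
            assert abs(dp[i, j] - (up - down) / (2 * h)) < 1e-4

    def test_bce_gradient(self, rng):
        p = rng.uniform(0.1, 0.9, size=6)
        loss, dp = nn.binary_cross_entropy(p, 1.0)
        h = 1e-7
        fd = np.zeros_like(p)
        for i in range(6):
            pp = p.copy(); pp[i] += h
            up, _ = nn.binary_cross_entropy(pp, 1.0)
            pp[i] -= 2 * h
            down, _ = nn.binary_cross_entropy(pp, 1.0)
            fd[i] = (up - down) / (2 * h)
        assert np.abs(dp - fd).max() < 1e-4

    def test_adam_and_sgd_reduce_quadratic_loss(self):
        for opt_cls, kwargs in [(nn.SGD, {"lr": 0.1}), (nn.Adam, {"lr": 0.1})]:
            p = nn.Param(np.array([3.0, -2.0]))
            opt = opt_cls([p], **kwargs)
            for _ in range(50):
                p.grad = 2 * p.value  # d/dp of sum(p^2)
                opt.step()
            assert np.sum(p.value**2) < 1.0

    def test_l2_coefficient_applied_by_optimizer(self):
        p = nn.Param(np.array([1.0]), l2=0.5)
        opt = nn.SGD([p], lr=1.0)
        p.grad = np.zeros(1)
        opt.step()  # update = lr * 2*l2*w = 1.0
        assert np.allclose(p.value, 0.0)
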