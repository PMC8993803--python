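import numpy as np
import pytest

from mammowave import nn
from mammowave.networks import (
    NetworkSpec, TrainConfig, build_cnn, build_wcnn, predict, train_model,
)
from mammowave.synthetic_mammo import SyntheticSpec, generate_dataset
from mammowave.wavelet_activation import WaveletActivation

SMALL = dict(input_size=16, n_blocks=2, convs_per_block=2,
             filters_per_block=(4, 8), n_classes=3)


def small_cnn(seed=0):
    return build_cnn(NetworkSpec(**SMALL), seed=seed)


def small_wcnn(seed=0):
    return build_wcnn(NetworkSpec(activation="wavelet", **SMALL), seed=seed)


class TestArchitecture:
    def test_default_has_18_conv_layers_of_3x3(self):
        model = build_cnn()
        convs = model.conv_layers()
        assert len(convs) == 18  # 6 blocks x 3 convolutions
        assert all(c.k == 3 for c in convs)
        assert all(c.W.l2 == 0.0002 for c in convs)

    def test_default_input_and_head(self):
        model = build_cnn()
        assert model.spec.input_size == 299
        dropouts = [l for l in model.net.layers if isinstance(l, nn.Dropout)]
        assert len(dropouts) == 1 and dropouts[0].rate == 0.5
        assert isinstance(model.net.layers[-1], nn.Softmax)
        assert isinstance(model.net.layers[-2], nn.Dense)

    def test_cnn_wcnn_parameter_counts_equal(self):
        assert build_cnn().n_parameters() == build_wcnn().n_parameters()

    def test_wcnn_uses_wavelet_activation_everywhere(self):
        model = build_wcnn(NetworkSpec(activation="wavelet", **SMALL))
        acts = [l for l in model.net.layers if isinstance(l, WaveletActivation)]
        assert len(acts) == 4  # one per convolution

    def test_activation_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(NetworkSpec(activation="wavelet", **SMALL))
        with pytest.raises(ValueError):
            build_wcnn(NetworkSpec(**SMALL))

    def test_spatial_collapse_rejected_at_build(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_size=16, n_blocks=5, convs_per_block=1,
                        filters_per_block=(2,) * 5)

    def test_filter_schedule_length_enforced(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_blocks=6, filters_per_block=(32, 64))


class TestForward:
    def test_softmax_rows_sum_to_one(self, rng):
        model = small_cnn()
        probs = model.forward(rng.random((2, 1, 16, 16)))
        assert probs.shape == (2, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_builds_are_identical(self, rng):
        x = rng.random((2, 1, 16, 16))
        assert np.array_equal(small_cnn(seed=5).forward(x), small_cnn(seed=5).forward(x))

    def test_cnn_and_wcnn_differ_on_nonzero_input(self, rng):
        x = rng.random((1, 1, 16, 16))
        assert not np.allclose(small_cnn(seed=5).forward(x),
                               small_wcnn(seed=5).forward(x))

    def test_zeroed_wcnn_first_activation_is_ones(self):
        model = small_wcnn()
        conv = model.net.layers[0]
        conv.W.value[...] = 0.0
        conv.b.value[...] = 0.0
        x = np.zeros((1, 1, 16, 16))
        first_act = model.net.layers[1].forward(conv.forward(x))
        assert np.all(first_act == 1.0)


def tiny_datasets():
    tr = generate_dataset(
        SyntheticSpec(image_size=32, class_counts={"N": 6, "M": 6}, seed=1),
        class_set=("N", "M"))
    va = generate_dataset(
        SyntheticSpec(image_size=32, class_counts={"N": 2, "M": 2}, seed=2),
        class_set=("N", "M"))
    return tr, va


def tiny_model(seed=0, activation="wavelet"):
    spec = NetworkSpec(input_size=32, n_blocks=2, convs_per_block=1,
                       filters_per_block=(4, 8), n_classes=2,
                       activation=activation)
    build = build_wcnn if activation == "wavelet" else build_cnn
    return build(spec, seed=seed, class_set=("N", "M"))


class TestTraining:
    def test_history_length_matches_epochs(self):
        tr, va = tiny_datasets()
        hist = train_model(tiny_model(), tr, va,
                           TrainConfig(epochs=3, batch_size=4, learning_rate=1e-3, seed=0))
        assert len(hist) == 3
        assert len(hist.val_accuracy) == 3
        assert all(np.isfinite(hist.loss))

    def test_zero_learning_rate_is_a_null_step(self, rng):
        tr, va = tiny_datasets()
        model = tiny_model(seed=4)
        x = rng.random((2, 1, 32, 32))
        before = model.forward(x)
        train_model(model, tr, va,
                    TrainConfig(epochs=1, batch_size=4, learning_rate=0.0, seed=0))
        assert np.array_equal(model.forward(x), before)

    def test_one_step_changes_loss_with_wavelet_activation(self):
        """No dead network at init: a single optimizer step moves the loss."""
        tr, va = tiny_datasets()
        model = tiny_model(seed=4)
        h = train_model(model, tr, None,
                        TrainConfig(epochs=2, batch_size=12, learning_rate=1e-2,
                                    seed=0, validation=False))
        assert h.loss[0] != h.loss[1]

    def test_seeded_training_is_deterministic(self):
        tr, va = tiny_datasets()
        cfg = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=9)
        h1 = train_model(tiny_model(seed=4), tr, va, cfg)
        h2 = train_model(tiny_model(seed=4), tr, va, cfg)
        assert h1.loss == h2.loss and h1.val_accuracy == h2.val_accuracy

    def test_empty_dataset_rejected(self):
        tr, va = tiny_datasets()
        from mammowave.synthetic_mammo import LabeledDataset
        empty = LabeledDataset((), class_set=("N", "M"))
        with pytest.raises(ValueError):
            train_model(tiny_model(), empty, va, TrainConfig(epochs=1))


class TestPredict:
    def test_single_image(self):
        tr, _ = tiny_datasets()
        model = tiny_model()
        probs, labels = predict(model, tr.samples[0].image)
        assert probs.shape == (1, 2)
        assert labels[0] in ("N", "M")

    def test_deterministic(self):
        tr, _ = tiny_datasets()
        model = tiny_model()
        p1, l1 = predict(model, tr)
        p2, l2 = predict(model, tr)
        assert np.array_equal(p1, p2) and l1 == l2

    def test_uniform_tie_breaks_to_first_class(self):
        tr, _ = tiny_datasets()
        model = tiny_model()
        for p in model.net.parameters():
            p.value[...] = 0.0  # uniform softmax output
        probs, labels = predict(model, tr.samples[0].image)
        assert np.allclose(probs, 0.5)
        assert labels[0] == "N"

    def test_shape_mismatch_rejected(self, rng):
        from mammowave.image_core import GrayImage
        model = tiny_model()
        with pytest.raises(ValueError):
            predict(model, GrayImage(rng.random((16, 16))))
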