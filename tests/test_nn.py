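"""CNN engine: backprop against numeric gradients, training behaviour,
inference determinism, prediction semantics."""

import numpy as np
import pytest

from cwtdcnn.arch import ArchitectureSpec, LayerSpec, default_architecture
from cwtdcnn.dcnn import TrainConfig, bce_loss, build_model, predict_labels, train_model
from cwtdcnn.nn.model import Model, sigmoid


def tiny_arch(dropout=0.0):
    return ArchitectureSpec(
        input_shape=(12, 14, 3),
        layers=(
            LayerSpec("rescale_resize", target=(12, 14)),
            LayerSpec("conv2d", kernel=3, filters=2, activation="relu"),
            LayerSpec("depthwise_conv2d", kernel=3, activation="relu"),
            LayerSpec("maxpool2d", kernel=2),
            LayerSpec("flatten"),
            LayerSpec("dropout", rate=dropout),
            LayerSpec("dense", units=5, activation="relu"),
            LayerSpec("dense", units=1, activation="sigmoid"),
        ),
    )


def test_backward_matches_numeric_gradient(rng):
    """Analytic gradients of every parameter agree with central finite
    differences of the binary cross-entropy loss (float64 model)."""
    model = Model(tiny_arch(), seed=3, dtype=np.float64)
    x = rng.random((4, 12, 14, 3))
    y = np.array([0.0, 1.0, 1.0, 0.0])

    def loss():
        z = model.forward(x, training=True, preprocessed=True)
        return bce_loss(z, y), z

    _, z = loss()
    model.backward((sigmoid(z) - y) / len(y))
    grads = [g.copy() for g in model.grads()]
    eps = 1e-6
    for p, g in zip(model.params(), grads):
        for _ in range(6):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up, _ = loss()
            p[idx] = orig - eps
            down, _ = loss()
            p[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-8)


def test_forward_probabilities_in_unit_interval(rng):
    model = build_model(default_architecture(input_size=(50, 70)))
    images = rng.integers(0, 256, size=(2, 500, 700, 3), dtype=np.uint8)
    p = model.predict_proba(images)
    assert p.shape == (2,)
    assert np.all((p >= 0) & (p <= 1))


def test_dropout_inactive_at_inference(rng):
    model = Model(tiny_arch(dropout=0.6), seed=0)
    x = rng.random((3, 12, 14, 3)).astype(np.float32)
    p1 = model.predict_proba(x, preprocessed=True)
    p2 = model.predict_proba(x, preprocessed=True)
    np.testing.assert_array_equal(p1, p2)


def test_dropout_active_in_training(rng):
    model = Model(tiny_arch(dropout=0.6), seed=0)
    x = rng.random((3, 12, 14, 3)).astype(np.float32)
    z1 = model.forward(x, training=True, preprocessed=True)
    z2 = model.forward(x, training=True, preprocessed=True)
    assert not np.array_equal(z1, z2)


def test_seeded_build_reproducible():
    m1 = Model(tiny_arch(), seed=11)
    m2 = Model(tiny_arch(), seed=11)
    for a, b in zip(m1.params(), m2.params()):
        np.testing.assert_array_equal(a, b)


class TestTraining:
    def _toy(self, rng, n=8):
        x = rng.random((n, 12, 14, 3)).astype(np.float32)
        y = (np.arange(n) % 2).astype(float)
        # make classes separable: positive samples brighter
        x[y == 1] = np.clip(x[y == 1] + 0.4, 0, 1)
        return x, y

    def test_history_length_one_epoch(self, rng):
        x, y = self._toy(rng, n=4)
        model = Model(tiny_arch(), seed=0)
        _, history = train_model(model, x, y, config=TrainConfig(epochs=1, batch_size=2),
                                 preprocessed=True)
        assert len(history["loss"]) == 1
        assert "val_loss" not in history

    def test_loss_decreases_on_toy_set(self, rng):
        x, y = self._toy(rng, n=16)
        model = Model(tiny_arch(), seed=1)
        _, history = train_model(
            model, x, y,
            config=TrainConfig(epochs=20, batch_size=8, learning_rate=5e-3, seed=1),
            preprocessed=True,
        )
        first = np.mean(history["loss"][:3])
        last = np.mean(history["loss"][-3:])
        assert last < first

    def test_training_reproducible_given_seed(self, rng):
        x, y = self._toy(rng)
        runs = []
        for _ in range(2):
            model = Model(tiny_arch(dropout=0.3), seed=5)
            model, _ = train_model(
                model, x, y, config=TrainConfig(epochs=3, batch_size=4, seed=5),
                preprocessed=True,
            )
            runs.append(model.predict_proba(x, preprocessed=True))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_eval_history_tracked(self, rng):
        x, y = self._toy(rng)
        model = Model(tiny_arch(), seed=0)
        _, history = train_model(
            model, x, y, x, y, config=TrainConfig(epochs=2, batch_size=4),
            preprocessed=True,
        )
        assert len(history["val_accuracy"]) == 2

    def test_rejects_bad_labels(self, rng):
        x, _ = self._toy(rng, n=4)
        model = Model(tiny_arch(), seed=0)
        with pytest.raises(ValueError, match="binary"):
            train_model(model, x, np.array([0, 1, 2, 1]), preprocessed=True)
        with pytest.raises(ValueError, match="empty"):
            train_model(model, x[:0], np.array([]), preprocessed=True)


class TestPredictLabels:
    @pytest.fixture
    def fitted(self, rng):
        model = Model(tiny_arch(), seed=0)
        x = rng.random((10, 12, 14, 3)).astype(np.float32)
        return model, x

    def test_boundary_counts_as_positive(self, fitted):
        model, x = fitted
        p = model.predict_proba(x, preprocessed=True)
        labels = predict_labels(model, x, threshold=float(p[0]), preprocessed=True)
        assert labels[0] == 1  # p >= threshold -> epilepsy

    def test_threshold_zero_all_positive(self, fitted):
        model, x = fitted
        assert predict_labels(model, x, threshold=0.0, preprocessed=True).all()

    def test_monotone_in_threshold(self, fitted):
        model, x = fitted
        counts = [
            predict_labels(model, x, threshold=t, preprocessed=True).sum()
            for t in np.linspace(0, 1, 11)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_optimizer_validation():
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)


def test_checkpoint_round_trip(tmp_path, rng):
    model = Model(tiny_arch(), seed=2)
    x = rng.random((3, 12, 14, 3)).astype(np.float32)
    path = model.save(tmp_path / "ckpt.pkl")
    restored = Model.load(path)
    np.testing.assert_array_equal(
        model.predict_proba(x, preprocessed=True),
        restored.predict_proba(x, preprocessed=True),
    )
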