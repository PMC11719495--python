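"""Build, train and apply the depthwise CNN classifier.

Training protocol defaults follow the study this package reproduces: Adam
with learning rate 0.0002, batch size 128, binary cross-entropy, up to 100
epochs, with a 75/25 train/eval split handled upstream. Labels are binary
with epilepsy encoded as 1 (the positive class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch import (
    ArchitectureSpec,
    count_parameters,
    default_architecture,
    propagate_shapes,
)
from .nn.model import Model, sigmoid

__all__ = [
    "TrainConfig",
    "build_model",
    "train_model",
    "predict_labels",
    "bce_loss",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 2e-4
    batch_size: int = 128
    epochs: int = 100
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError("optimizer must be 'adam' or 'rmsprop'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")


def build_model(arch: ArchitectureSpec | None = None, config: TrainConfig | None = None) -> Model:
    """Instantiate the network with seeded weights.

    The runtime model's layer shapes are guaranteed to equal the analytic
    :func:`~cwtdcnn.arch.propagate_shapes` output (same fold drives both).
    """
    arch = arch or default_architecture()
    config = config or TrainConfig()
    return Model(arch, seed=config.seed)


def bce_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy evaluated stably from logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0 = normal, 1 = epilepsy)")
    return y.astype(np.float64)


def train_model(
    model: Model,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    eval_images: np.ndarray | None = None,
    eval_labels: np.ndarray | None = None,
    config: TrainConfig | None = None,
    preprocessed: bool = False,
) -> tuple[Model, dict[str, list[float]]]:
    """Minimize binary cross-entropy by mini-batch gradient descent.

    Returns the fitted model plus a history dict with per-epoch
    ``loss``/``accuracy`` and, when an eval set is given, ``val_loss``/
    ``val_accuracy``. Shuffling and dropout are seeded via ``config.seed``;
    images are resized/scaled once up front.
    """
    from .nn.optim import make_optimizer

    config = config or TrainConfig()
    y = _check_labels(train_labels)
    x = model.preprocess(train_images) if not preprocessed else np.asarray(
        train_images, dtype=np.float32
    )
    if x.shape[0] != y.shape[0]:
        raise ValueError("image/label count mismatch")
    has_eval = eval_images is not None
    if has_eval:
        ye = _check_labels(eval_labels)
        xe = model.preprocess(eval_images) if not preprocessed else np.asarray(
            eval_images, dtype=np.float32
        )

    optimizer = make_optimizer(config.optimizer, model.params(), config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if has_eval:
        history["val_loss"] = []
        history["val_accuracy"] = []

    n = x.shape[0]
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, training=True, preprocessed=True)
            p = sigmoid(logits)
            model.backward((p - yb) / len(idx))
            optimizer.step(model.grads())
            epoch_loss += bce_loss(logits, yb) * len(idx)
            epoch_correct += int(((p >= config.threshold) == yb.astype(bool)).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)
        if has_eval:
            pe = model.predict_proba(xe, preprocessed=True)
            with np.errstate(divide="ignore"):
                val_loss = float(
                    -np.mean(ye * np.log(np.clip(pe, 1e-12, 1))
                             + (1 - ye) * np.log(np.clip(1 - pe, 1e-12, 1)))
                )
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(
                float(np.mean((pe >= config.threshold) == ye.astype(bool)))
            )
    return model, history


def predict_labels(
    model: Model,
    images: np.ndarray,
    threshold: float = 0.5,
    preprocessed: bool = False,
) -> np.ndarray:
    """Binary labels: epilepsy (1) iff sigmoid output >= ``threshold``."""
    p = model.predict_proba(images, preprocessed=preprocessed)
    return (p >= threshold).astype(np.int64)
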