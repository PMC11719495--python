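"""Runtime model assembled from an :class:`~cwtdcnn.arch.ArchitectureSpec`.

The first (rescale_resize) layer is deterministic preprocessing: bilinear
resize of any input image to the target (H, W) and division by 255, mapping
8-bit composites to [0, 1]. It carries no parameters and needs no gradient,
so it is applied outside the differentiable stack; callers that loop over
the same images many times can preprocess once and pass ``preprocessed=True``.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .._resize import bilinear_resize
from ..arch import ArchitectureSpec, propagate_shapes, shape_after_layer
from . import layers as L

__all__ = ["Model"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Model:
    """Sequential network with a sigmoid binary head.

    ``forward`` returns logits; ``predict_proba`` applies the sigmoid.
    Layer output shapes are exposed as ``layer_shapes`` (one entry per
    architecture layer, matching the analytic propagation).
    """

    def __init__(self, arch: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        arch.validate_binary_head()
        self.arch = arch
        self.dtype = np.dtype(dtype)
        self.layer_shapes = propagate_shapes(arch)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

        if arch.layers[0].kind != "rescale_resize":
            raise ValueError("architecture must start with a rescale_resize layer")
        self.target_hw: tuple[int, int] = arch.layers[0].target

        self.layers: list[L.Layer] = []
        shape = self.layer_shapes[0]
        for spec in arch.layers[1:]:
            if spec.kind == "conv2d":
                layer = L.Conv2D(spec.kernel, shape[2], spec.filters, spec.activation,
                                 rng, dtype=self.dtype)
            elif spec.kind == "depthwise_conv2d":
                layer = L.DepthwiseConv2D(spec.kernel, shape[2], spec.activation,
                                          rng, dtype=self.dtype)
            elif spec.kind == "maxpool2d":
                layer = L.MaxPool2D(spec.kernel)
            elif spec.kind == "flatten":
                layer = L.Flatten()
            elif spec.kind == "dropout":
                layer = L.Dropout(spec.rate, self.dropout_rng)
            elif spec.kind == "dense":
                layer = L.Dense(shape[0], spec.units, spec.activation, rng,
                                dtype=self.dtype)
            elif spec.kind == "rescale_resize":
                raise ValueError("rescale_resize is only valid as the first layer")
            else:  # pragma: no cover - LayerSpec already validates
                raise ValueError(spec.kind)
            self.layers.append(layer)
            shape = shape_after_layer(spec, shape)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    # -- forward / backward -------------------------------------------------

    def preprocess(self, images: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Resize a batch of (N, H, W, 3) images to the target and map to [0, 1]."""
        images = np.asarray(images)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError("expected an (N, H, W, 3) image batch")
        h, w = self.target_hw
        out = np.empty((images.shape[0], h, w, 3), dtype=self.dtype)
        for start in range(0, images.shape[0], chunk):
            block = images[start : start + chunk]
            for i, img in enumerate(block):
                out[start + i] = bilinear_resize(img, (h, w))
        out /= 255.0
        return out

    def forward(
        self, x: np.ndarray, training: bool = False, preprocessed: bool = False
    ) -> np.ndarray:
        """Run the network; returns logits of shape (N,)."""
        if not preprocessed:
            x = self.preprocess(x)
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x[:, 0]

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = np.asarray(grad_logits, dtype=self.dtype)[:, None]
        for pos, layer in reversed(list(enumerate(self.layers))):
            grad = layer.backward(grad, need_input_grad=pos > 0)

    def predict_proba(
        self, images: np.ndarray, preprocessed: bool = False, batch: int = 64
    ) -> np.ndarray:
        """Epilepsy-class probabilities in [0, 1] (inference mode)."""
        images = np.asarray(images)
        probs = np.empty(images.shape[0], dtype=np.float64)
        for start in range(0, images.shape[0], batch):
            z = self.forward(
                images[start : start + batch], training=False, preprocessed=preprocessed
            )
            probs[start : start + batch] = sigmoid(z)
        return probs

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Checkpoint architecture + weights (pickle of plain arrays)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump({"arch": self.arch, "params": self.params()}, fh)
        return path

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "Model":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["arch"], seed=seed)
        for p, saved in zip(model.params(), blob["params"]):
            p[...] = saved
        return model
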