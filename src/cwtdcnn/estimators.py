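"""scikit-learn estimators wrapping the scalogram pipeline and the CNN.

``ScalogramCompositeTransformer`` turns raw (n_segments, 35, T) EEG arrays
into composite scalogram images; ``DepthwiseCNNClassifier`` fits the
depthwise CNN on such images. Both follow the sklearn protocol
(get_params/set_params, fitted attributes with trailing underscores) and
compose in a :class:`sklearn.pipeline.Pipeline`:

    Pipeline([
        ("images", ScalogramCompositeTransformer(resize_to=(100, 140))),
        ("cnn", DepthwiseCNNClassifier(input_size=(100, 140), epochs=15)),
    ])
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from ._resize import bilinear_resize
from .arch import default_architecture
from .dcnn import TrainConfig, build_model, train_model
from .scalogram import CWTParams, _cwt_batch, _render_batch, demean
from .synthetic import EEGSegment
from .tiler import TileLayout, compose

__all__ = ["ScalogramCompositeTransformer", "DepthwiseCNNClassifier"]


def _segments_to_array(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        arr = X
    else:
        first = X[0]
        if isinstance(first, EEGSegment):
            arr = np.stack([seg.samples for seg in X])
        else:
            arr = np.asarray(X)
    if arr.ndim != 3:
        raise ValueError("expected (n_segments, n_channels, T) EEG data")
    return arr.astype(np.float64, copy=False)


class ScalogramCompositeTransformer(TransformerMixin, BaseEstimator):
    """EEG segments -> tiled scalogram images.

    Each of the 35 channels is CWT-transformed over ``scales`` (default
    1..100), magnitude-normalized, jet-colormapped and resized to a
    ``tile_hw`` tile; tiles are concatenated into a 7x5 grid. With
    ``resize_to=None`` the output is the uint8 composite batch
    (n, 500, 700, 3); with ``resize_to=(h, w)`` the composite is further
    bilinearly resized and scaled to [0, 1] float32 — exactly the CNN's
    input rescaling layer, precomputed once.

    Stateless: ``fit`` only validates parameters.
    """

    def __init__(
        self,
        scales: np.ndarray | None = None,
        tile_hw: tuple[int, int] = (100, 100),
        n_cols: int = 7,
        n_rows: int = 5,
        resize_to: tuple[int, int] | None = None,
    ):
        self.scales = scales
        self.tile_hw = tile_hw
        self.n_cols = n_cols
        self.n_rows = n_rows
        self.resize_to = resize_to

    def _params(self) -> CWTParams:
        if self.scales is None:
            return CWTParams()
        return CWTParams(scales=np.asarray(self.scales, dtype=np.float64))

    def _layout(self) -> TileLayout:
        return TileLayout(n_cols=self.n_cols, n_rows=self.n_rows, tile_size=self.tile_hw)

    def fit(self, X=None, y=None):
        self._params()
        layout = self._layout()
        self.n_channels_ = layout.n_tiles
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_channels_"):
            self.fit(X)
        arr = _segments_to_array(X)
        layout = self._layout()
        if arr.shape[1] != layout.n_tiles:
            raise ValueError(
                f"expected {layout.n_tiles} channels for a "
                f"{layout.n_cols}x{layout.n_rows} grid, got {arr.shape[1]}"
            )
        params = self._params()
        n = arr.shape[0]
        if self.resize_to is None:
            out = np.empty((n, *layout.composite_shape), dtype=np.uint8)
        else:
            out = np.empty((n, *self.resize_to, 3), dtype=np.float32)
        for s in range(n):
            chans = demean(arr[s])
            coefs = _cwt_batch(chans, params, dtype=np.float32)  # (35, S, T)
            tiles = _render_batch(np.abs(coefs), layout.tile_size)
            composite = compose(list(tiles), layout)
            if self.resize_to is None:
                out[s] = composite
            else:
                out[s] = bilinear_resize(composite, self.resize_to) / 255.0
        return out


class DepthwiseCNNClassifier(ClassifierMixin, BaseEstimator):
    """Depthwise-CNN binary classifier over composite scalogram images.

    Parameters mirror the training protocol: ``optimizer`` ('adam' or
    'rmsprop'), ``learning_rate`` (default 0.0002), ``batch_size`` (128),
    ``epochs`` (100), ``dropout`` (0.6) and the in-network resize target
    ``input_size`` (one of 50x70, 100x140, 150x210, 200x280 in the studied
    grid, default 150x210). ``X`` may be uint8 images of any size (resized
    in-network) or float32 batches already at ``input_size`` scaled to
    [0, 1] (detected automatically and used as-is).

    Fitted attributes: ``model_`` (the network), ``history_`` (per-epoch
    loss/accuracy), ``classes_``.
    """

    def __init__(
        self,
        input_size: tuple[int, int] = (150, 210),
        optimizer: str = "adam",
        learning_rate: float = 2e-4,
        batch_size: int = 128,
        epochs: int = 100,
        dropout: float = 0.6,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.threshold = threshold
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.random_state,
            threshold=self.threshold,
        )

    def _is_preprocessed(self, X: np.ndarray) -> bool:
        return (
            np.issubdtype(X.dtype, np.floating)
            and X.shape[1:3] == tuple(self.input_size)
            and float(X.max(initial=0.0)) <= 1.0 + 1e-6
        )

    def fit(self, X, y, eval_set: tuple[np.ndarray, np.ndarray] | None = None):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must be an (n, H, W, 3) image batch")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        config = self._train_config()
        arch = default_architecture(input_size=tuple(self.input_size), dropout=self.dropout)
        model = build_model(arch, config)
        pre = self._is_preprocessed(X)
        eval_images = eval_labels = None
        if eval_set is not None:
            eval_images, eval_labels = eval_set
        self.model_, self.history_ = train_model(
            model, X, y, eval_images, eval_labels, config, preprocessed=pre
        )
        self.classes_ = np.array([0, 1])
        self.n_parameters_ = self.model_.n_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        X = np.asarray(X)
        p = self.model_.predict_proba(X, preprocessed=self._is_preprocessed(X))
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.threshold).astype(int)]
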