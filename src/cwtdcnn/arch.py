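"""Declarative CNN architecture with analytic shape/parameter accounting.

The network is the lightweight depthwise CNN used for composite-scalogram
classification:

    rescale_resize -> (150, 210, 3)
    conv2d 3x3, 4 filters, relu
    depthwise 5x5, relu
    conv2d 3x3, 8 filters, relu
    maxpool 2x2
    depthwise 5x5, relu
    maxpool 2x2
    flatten
    dropout 0.6
    dense 512, relu
    dense 1, sigmoid

Convolutions use valid padding and stride 1 (H' = H - k + 1); depthwise
layers have channel multiplier 1 (channel count preserved); max pooling is
2x2 with stride 2 and floor division. These conventions are forced by the
layer-by-layer output shapes the architecture is defined to produce.

The same :class:`ArchitectureSpec` drives both this module's pure
propagation (:func:`propagate_shapes`, :func:`count_parameters`) and the
runtime model built by :mod:`cwtdcnn.nn` — two independent routes that are
cross-checked in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "default_architecture",
    "shape_after_layer",
    "propagate_shapes",
    "count_parameters",
]

_KINDS = {
    "rescale_resize",
    "conv2d",
    "depthwise_conv2d",
    "maxpool2d",
    "flatten",
    "dropout",
    "dense",
}


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    kernel: int | None = None  # square kernel side, conv/depthwise/pool
    filters: int | None = None  # conv2d output channels
    units: int | None = None  # dense width
    activation: str | None = None  # relu | sigmoid | None
    rate: float | None = None  # dropout fraction
    target: tuple[int, int] | None = None  # rescale_resize output (H, W)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv2d", "depthwise_conv2d"):
            if self.kernel is None or self.kernel < 1 or self.kernel % 2 == 0:
                raise ValueError(f"{self.kind} kernel must be odd and >= 1")
        if self.kind == "conv2d" and (self.filters is None or self.filters < 1):
            raise ValueError("conv2d needs a positive filter count")
        if self.kind == "maxpool2d" and (self.kernel is None or self.kernel < 1):
            raise ValueError("maxpool2d needs a positive pool size")
        if self.kind == "dense" and (self.units is None or self.units < 1):
            raise ValueError("dense needs a positive unit count")
        if self.kind == "dropout":
            if self.rate is None or not (0.0 <= self.rate < 1.0):
                raise ValueError("dropout rate must be in [0, 1)")
        if self.kind == "rescale_resize" and self.target is None:
            raise ValueError("rescale_resize needs a target (H, W)")
        if self.activation not in (None, "relu", "sigmoid"):
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Input shape plus ordered layer list."""

    input_shape: tuple[int, int, int] = (500, 700, 3)
    layers: tuple[LayerSpec, ...] = ()

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("architecture needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    def validate_binary_head(self) -> None:
        last = self.layers[-1]
        if not (last.kind == "dense" and last.units == 1 and last.activation == "sigmoid"):
            raise ValueError("binary task requires a dense(1, sigmoid) head")


def default_architecture(
    input_size: tuple[int, int] = (150, 210),
    input_shape: tuple[int, int, int] = (500, 700, 3),
    dropout: float = 0.6,
) -> ArchitectureSpec:
    """The standard depthwise CNN, parameterized by the resize target.

    ``input_size`` is the (H, W) the rescaling layer maps composites to;
    the studied grid is 50x70, 100x140, 150x210 (default) and 200x280.
    """
    return ArchitectureSpec(
        input_shape=input_shape,
        layers=(
            LayerSpec("rescale_resize", target=tuple(input_size)),
            LayerSpec("conv2d", kernel=3, filters=4, activation="relu"),
            LayerSpec("depthwise_conv2d", kernel=5, activation="relu"),
            LayerSpec("conv2d", kernel=3, filters=8, activation="relu"),
            LayerSpec("maxpool2d", kernel=2),
            LayerSpec("depthwise_conv2d", kernel=5, activation="relu"),
            LayerSpec("maxpool2d", kernel=2),
            LayerSpec("flatten"),
            LayerSpec("dropout", rate=dropout),
            LayerSpec("dense", units=512, activation="relu"),
            LayerSpec("dense", units=1, activation="sigmoid"),
        ),
    )


def shape_after_layer(layer: LayerSpec, in_shape: tuple) -> tuple:
    """Output shape of one layer given its input shape (no batch axis)."""
    if layer.kind == "rescale_resize":
        if len(in_shape) != 3:
            raise ValueError("rescale_resize expects an (H, W, C) input")
        return (*layer.target, in_shape[2])
    if layer.kind in ("conv2d", "depthwise_conv2d"):
        if len(in_shape) != 3:
            raise ValueError(f"{layer.kind} expects an (H, W, C) input")
        h, w, c = in_shape
        k = layer.kernel
        if k > h or k > w:
            raise ValueError(f"kernel {k}x{k} larger than input {h}x{w}")
        h_out, w_out = h - k + 1, w - k + 1
        return (h_out, w_out, layer.filters if layer.kind == "conv2d" else c)
    if layer.kind == "maxpool2d":
        h, w, c = in_shape
        k = layer.kernel
        if h < k or w < k:
            raise ValueError(f"pool {k}x{k} larger than input {h}x{w}")
        return (h // k, w // k, c)
    if layer.kind == "flatten":
        n = 1
        for d in in_shape:
            n *= d
        return (n,)
    if layer.kind == "dropout":
        return tuple(in_shape)
    if layer.kind == "dense":
        if len(in_shape) != 1:
            raise ValueError("dense expects a flat input")
        return (layer.units,)
    raise AssertionError(layer.kind)


def propagate_shapes(arch: ArchitectureSpec) -> list[tuple]:
    """Fold :func:`shape_after_layer` over the network; one shape per layer."""
    shapes = []
    shape = tuple(arch.input_shape)
    for layer in arch.layers:
        shape = shape_after_layer(layer, shape)
        shapes.append(shape)
    return shapes


def layer_parameters(layer: LayerSpec, in_shape: tuple) -> int:
    """Trainable parameters contributed by one layer.

    conv2d: k^2 * C_in * C_out + C_out; depthwise (multiplier 1):
    k^2 * C + C; dense: n_in * n_out + n_out; all other kinds 0.
    """
    if layer.kind == "conv2d":
        k, c_in = layer.kernel, in_shape[2]
        return k * k * c_in * layer.filters + layer.filters
    if layer.kind == "depthwise_conv2d":
        k, c = layer.kernel, in_shape[2]
        return k * k * c + c
    if layer.kind == "dense":
        return in_shape[0] * layer.units + layer.units
    return 0


def count_parameters(arch: ArchitectureSpec) -> int:
    """Total trainable parameter count of the architecture."""
    total = 0
    shape = tuple(arch.input_shape)
    for layer in arch.layers:
        total += layer_parameters(layer, shape)
        shape = shape_after_layer(layer, shape)
    return total
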