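"""Analytic shape propagation and parameter counting."""

import numpy as np
import pytest

from cwtdcnn.arch import (
    ArchitectureSpec,
    LayerSpec,
    count_parameters,
    default_architecture,
    layer_parameters,
    propagate_shapes,
    shape_after_layer,
)

# Layer-by-layer output shapes of the standard network at its default
# 150x210 input, ending in the 12,672-wide flatten and the binary head.
REFERENCE_SHAPES = [
    (150, 210, 3),
    (148, 208, 4),
    (144, 204, 4),
    (142, 202, 8),
    (71, 101, 8),
    (67, 97, 8),
    (33, 48, 8),
    (12672,),
    (12672,),
    (512,),
    (1,),
]


class TestShapePropagation:
    def test_default_architecture_reference_shapes(self):
        assert propagate_shapes(default_architecture()) == REFERENCE_SHAPES

    @pytest.mark.parametrize(
        "layer,in_shape,expected",
        [
            (LayerSpec("conv2d", kernel=3, filters=4, activation="relu"),
             (150, 210, 3), (148, 208, 4)),
            (LayerSpec("maxpool2d", kernel=2), (142, 202, 8), (71, 101, 8)),
            (LayerSpec("maxpool2d", kernel=2), (67, 97, 8), (33, 48, 8)),
            (LayerSpec("depthwise_conv2d", kernel=5), (148, 208, 4), (144, 204, 4)),
            (LayerSpec("flatten"), (33, 48, 8), (12672,)),
            (LayerSpec("dense", units=512, activation="relu"), (12672,), (512,)),
        ],
    )
    def test_single_layer_rules(self, layer, in_shape, expected):
        assert shape_after_layer(layer, in_shape) == expected

    def test_small_input_fold(self):
        # independent hand-fold: 50x70 -> 48x68 -> 44x64 -> 42x62 -> 21x31
        # -> 17x27 -> 8x13; 8*13*8 = 832
        arch = default_architecture(input_size=(50, 70))
        shapes = propagate_shapes(arch)
        assert shapes[1:7] == [
            (48, 68, 4), (44, 64, 4), (42, 62, 8), (21, 31, 8), (17, 27, 8), (8, 13, 8)
        ]
        assert shapes[7] == (832,)

    def test_kernel_larger_than_input(self):
        layer = LayerSpec("conv2d", kernel=5, filters=1, activation="relu")
        with pytest.raises(ValueError, match="larger"):
            shape_after_layer(layer, (3, 3, 1))


class TestParameterCount:
    def test_depthwise_example(self):
        layer = LayerSpec("depthwise_conv2d", kernel=5)
        assert layer_parameters(layer, (10, 10, 4)) == 25 * 4 + 4  # 104

    def test_dense_example(self):
        layer = LayerSpec("dense", units=512, activation="relu")
        assert layer_parameters(layer, (12672,)) == 12672 * 512 + 512  # 6,488,576

    def test_default_total(self):
        # per-layer sum: 112 + 104 + 296 + 208 + 6,488,576 + 513
        assert count_parameters(default_architecture()) == 6_489_809

    def test_pool_and_flatten_free(self):
        assert layer_parameters(LayerSpec("maxpool2d", kernel=2), (4, 4, 2)) == 0
        assert layer_parameters(LayerSpec("flatten"), (4, 4, 2)) == 0
        assert layer_parameters(LayerSpec("dropout", rate=0.5), (32,)) == 0


class TestLayerSpecValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            LayerSpec("conv2d", kernel=4, filters=2)

    def test_dropout_rate_bounds(self):
        with pytest.raises(ValueError):
            LayerSpec("dropout", rate=1.0)
        with pytest.raises(ValueError):
            LayerSpec("dropout")

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            LayerSpec("transposed_conv")

    def test_binary_head_required(self):
        arch = ArchitectureSpec(
            layers=(
                LayerSpec("rescale_resize", target=(10, 10)),
                LayerSpec("flatten"),
                LayerSpec("dense", units=2, activation="sigmoid"),
            )
        )
        with pytest.raises(ValueError, match="sigmoid"):
            arch.validate_binary_head()


def random_valid_arch(rng) -> ArchitectureSpec:
    """Random small architecture that always propagates."""
    h = int(rng.integers(30, 60))
    w = int(rng.integers(30, 60))
    layers = [LayerSpec("rescale_resize", target=(h, w))]
    c = 3
    for _ in range(int(rng.integers(1, 4))):
        kind = rng.choice(["conv2d", "depthwise_conv2d", "maxpool2d"])
        if kind == "conv2d":
            c = int(rng.integers(2, 6))
            layers.append(LayerSpec("conv2d", kernel=3, filters=c, activation="relu"))
        elif kind == "depthwise_conv2d":
            layers.append(LayerSpec("depthwise_conv2d", kernel=3, activation="relu"))
        else:
            layers.append(LayerSpec("maxpool2d", kernel=2))
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", units=int(rng.integers(4, 17)), activation="relu"),
        LayerSpec("dense", units=1, activation="sigmoid"),
    ]
    return ArchitectureSpec(input_shape=(100, 100, 3), layers=tuple(layers))


def test_engine_agrees_with_analytic_propagation_on_random_archs(rng):
    """The runtime model's actual tensor shapes and its trainable-parameter
    total equal the analytic fold, over 20 random architectures."""
    from cwtdcnn.nn.model import Model

    for _ in range(20):
        arch = random_valid_arch(rng)
        model = Model(arch, seed=0)
        shapes = propagate_shapes(arch)
        x = rng.random((2, *arch.input_shape)).astype(np.float32)
        h = model.preprocess(x)
        assert h.shape[1:] == shapes[0]
        for layer, expected in zip(model.layers, shapes[1:]):
            h = layer.forward(h)
            assert h.shape[1:] == expected
        assert model.n_parameters() == count_parameters(arch)
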