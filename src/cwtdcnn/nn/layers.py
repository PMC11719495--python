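"""Layer implementations: NHWC tensors, float32, explicit backprop.

Convolutions are evaluated as k*k shifted GEMM accumulations (one matrix
product per kernel offset), which keeps peak memory far below an im2col
buffer while staying inside BLAS for the heavy lifting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "DepthwiseConv2D", "MaxPool2D", "Flatten", "Dropout", "Dense"]


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base: parameter-free identity; subclasses override as needed."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        raise NotImplementedError


def _apply_relu(layer, y: np.ndarray, training: bool) -> np.ndarray:
    if layer.activation == "relu":
        np.maximum(y, 0.0, out=y)
        if training:
            layer._act_mask = y > 0
    return y


def _relu_grad(layer, grad: np.ndarray) -> np.ndarray:
    if layer.activation == "relu":
        grad = grad * layer._act_mask
    return grad


class Conv2D(Layer):
    """Standard 2-D convolution, valid padding, stride 1.

    Weights (k, k, C_in, C_out) mix all input channels into each of the
    C_out feature maps.
    """

    def __init__(self, kernel: int, c_in: int, c_out: int, activation: str | None,
                 rng: np.random.Generator, dtype=np.float32):
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        self.activation = activation
        fan_in = kernel * kernel * c_in
        self.w = _he_normal(rng, (kernel, kernel, c_in, c_out), fan_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        n, h, w_in, _ = x.shape
        k = self.k
        ho, wo = h - k + 1, w_in - k + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"kernel {k}x{k} larger than input {h}x{w_in}")
        # im2col: one contiguous (N*H'*W', k*k*C_in) patch matrix, one GEMM
        cols = np.empty((n, ho, wo, k * k * self.c_in), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                c0 = (i * k + j) * self.c_in
                cols[..., c0 : c0 + self.c_in] = x[:, i : i + ho, j : j + wo, :]
        cols = cols.reshape(-1, k * k * self.c_in)
        y = cols @ self.w.reshape(-1, self.c_out)
        y += self.b
        y = y.reshape(n, ho, wo, self.c_out)
        if training:
            self._cols = cols
            self._in_shape = x.shape
        return _apply_relu(self, y, training)

    def backward(self, grad, need_input_grad=True):
        grad = _relu_grad(self, grad)
        n, h, w_in, _ = self._in_shape
        k = self.k
        ho, wo = grad.shape[1], grad.shape[2]
        gflat = np.ascontiguousarray(grad.reshape(-1, self.c_out))
        self.db[:] = gflat.sum(axis=0)
        self.dw[:] = (self._cols.T @ gflat).reshape(self.dw.shape)
        self._cols = None
        if not need_input_grad:
            return None
        dcols = (gflat @ self.w.reshape(-1, self.c_out).T).reshape(
            n, ho, wo, k * k, self.c_in
        )
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i * k + j, :]
        return dx


class DepthwiseConv2D(Layer):
    """Depthwise convolution: one k x k filter per channel, multiplier 1.

    Each input channel is filtered independently, so the channel count is
    preserved and the layer costs k^2 * C (+C bias) parameters instead of a
    standard convolution's k^2 * C * N.
    """

    def __init__(self, kernel: int, c: int, activation: str | None,
                 rng: np.random.Generator, dtype=np.float32):
        self.k, self.c = kernel, c
        self.activation = activation
        self.w = _he_normal(rng, (kernel, kernel, c), kernel * kernel, dtype)
        self.b = np.zeros(c, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        n, h, w_in, c = x.shape
        k = self.k
        ho, wo = h - k + 1, w_in - k + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"kernel {k}x{k} larger than input {h}x{w_in}")
        y = np.broadcast_to(self.b, (n, ho, wo, c)).astype(self.w.dtype).copy()
        for i in range(k):
            for j in range(k):
                y += x[:, i : i + ho, j : j + wo, :] * self.w[i, j]
        if training:
            self._x = x
        return _apply_relu(self, y, training)

    def backward(self, grad, need_input_grad=True):
        grad = _relu_grad(self, grad)
        x = self._x
        k = self.k
        ho, wo = grad.shape[1], grad.shape[2]
        grad = np.ascontiguousarray(grad)
        self.db[:] = grad.sum(axis=(0, 1, 2))
        gflat = grad.reshape(-1, self.c)
        dx = np.zeros_like(x) if need_input_grad else None
        buf = np.empty((gflat.shape[0], self.c), dtype=x.dtype)
        prod = np.empty_like(grad)
        for i in range(k):
            for j in range(k):
                np.copyto(buf.reshape(grad.shape), x[:, i : i + ho, j : j + wo, :])
                buf *= gflat
                self.dw[i, j] = buf.sum(axis=0)
                if need_input_grad:
                    np.multiply(grad, self.w[i, j], out=prod)
                    dx[:, i : i + ho, j : j + wo, :] += prod
        return dx


class MaxPool2D(Layer):
    """k x k max pooling with stride k; trailing rows/cols are dropped."""

    def __init__(self, kernel: int):
        self.k = kernel

    def forward(self, x, training=False):
        n, h, w_in, c = x.shape
        k = self.k
        ho, wo = h // k, w_in // k
        if ho < 1 or wo < 1:
            raise ValueError(f"pool {k}x{k} larger than input {h}x{w_in}")
        windows = (
            x[:, : ho * k, : wo * k, :]
            .reshape(n, ho, k, wo, k, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, ho, wo, c, k * k)
        )
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if training:
            # flat index of each window's maximum in the input tensor
            ni, hi, wi, ci = np.ogrid[0:n, 0:ho, 0:wo, 0:c]
            src_h = hi * k + idx // k
            src_w = wi * k + idx % k
            self._flat = (((ni * h + src_h) * w_in + src_w) * c + ci).ravel()
            self._in_shape = x.shape
        return out

    def backward(self, grad, need_input_grad=True):
        dx = np.zeros(int(np.prod(self._in_shape)), dtype=grad.dtype)
        dx[self._flat] = grad.ravel()
        return dx.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x, training=False):
        if training:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, need_input_grad=True):
        return grad.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad, need_input_grad=True):
        if self.rate == 0.0:
            return grad
        return grad * self._mask


class Dense(Layer):
    """Fully connected layer.

    A ``sigmoid`` activation marks the binary head: the layer itself emits
    logits (the model applies the sigmoid at prediction time and the
    training loss is fused sigmoid + binary cross-entropy for stability).
    """

    def __init__(self, n_in: int, n_out: int, activation: str | None,
                 rng: np.random.Generator, dtype=np.float32):
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        if activation == "sigmoid":
            self.w = _glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        else:
            self.w = _he_normal(rng, (n_in, n_out), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        y = x @ self.w + self.b
        if training:
            self._x = x
        return _apply_relu(self, y, training)

    def backward(self, grad, need_input_grad=True):
        grad = _relu_grad(self, grad)
        self.dw[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        if not need_input_grad:
            return None
        return grad @ self.w.T
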