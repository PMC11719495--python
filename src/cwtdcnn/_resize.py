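"""Bilinear image resizing with half-pixel-centre sampling.

One deterministic resampler is shared by the scalogram renderer (scale x time
coefficient field -> 100x100 tile) and the network's input rescaling layer
(500x700 composite -> e.g. 150x210). Half-pixel centres: output pixel j maps
to source coordinate (j + 0.5) * (in/out) - 0.5, clamped to the valid range,
which treats both axes as independently stretchable ("aspect auto").
"""

from __future__ import annotations

import numpy as np


def _axis_weights(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (lo index, hi index, hi weight) for one axis."""
    if n_in < 1 or n_out < 1:
        raise ValueError("resize axes must be positive")
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(np.intp)
    hi = np.minimum(lo + 1, n_in - 1)
    w = src - lo
    return lo, hi, w


def bilinear_resize(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Resize an (H, W) or (H, W, C) array to ``out_hw`` = (H', W').

    Pure gather-and-lerp; float64 accumulation; the caller decides any
    quantization. Input dtype is preserved only in value range, the result
    is float64.
    """
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-D image, got shape {img.shape}")
    h_out, w_out = int(out_hw[0]), int(out_hw[1])
    ylo, yhi, wy = _axis_weights(img.shape[0], h_out)
    xlo, xhi, wx = _axis_weights(img.shape[1], w_out)
    a = img.astype(np.float64, copy=False)
    if a.ndim == 3:
        wx_ = wx[None, :, None]
        wy_ = wy[:, None, None]
        top = a[ylo][:, xlo] * (1 - wx_) + a[ylo][:, xhi] * wx_
        bot = a[yhi][:, xlo] * (1 - wx_) + a[yhi][:, xhi] * wx_
        return top * (1 - wy_) + bot * wy_
    wx_ = wx[None, :]
    wy_ = wy[:, None]
    top = a[ylo][:, xlo] * (1 - wx_) + a[ylo][:, xhi] * wx_
    bot = a[yhi][:, xlo] * (1 - wx_) + a[yhi][:, xhi] * wx_
    return top * (1 - wy_) + bot * wy_


def bilinear_resize_batch(imgs: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Resize an (N, H, W, C) batch with the same geometry as
    :func:`bilinear_resize`, interpolating columns first to shrink the
    working set. Result dtype follows the input's floating type (float32
    stays float32)."""
    imgs = np.asarray(imgs)
    if imgs.ndim != 4:
        raise ValueError(f"expected an (N, H, W, C) batch, got shape {imgs.shape}")
    h_out, w_out = int(out_hw[0]), int(out_hw[1])
    ylo, yhi, wy = _axis_weights(imgs.shape[1], h_out)
    xlo, xhi, wx = _axis_weights(imgs.shape[2], w_out)
    dtype = imgs.dtype if np.issubdtype(imgs.dtype, np.floating) else np.float64
    a = imgs.astype(dtype, copy=False)
    wx_ = wx.astype(dtype)[None, None, :, None]
    wy_ = wy.astype(dtype)[None, :, None, None]
    cols = a[:, :, xlo] * (1 - wx_) + a[:, :, xhi] * wx_          # (N, H, W', C)
    return cols[:, ylo] * (1 - wy_) + cols[:, yhi] * wy_          # (N, H', W', C)
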