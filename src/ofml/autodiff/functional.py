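"""Spatial primitives (convolution, pooling) for the autodiff engine.

Convolution is implemented by im2col + matmul: the input is unfolded into a
matrix of receptive-field columns with ``sliding_window_view`` (a strided
view, no copy until the matmul), the kernel acts as a single dense matrix,
and the backward pass folds column gradients back with per-offset
scatter-adds.  This keeps both passes inside BLAS and makes the gradients
exact rather than approximated.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import DEFAULT_DTYPE, Tensor


def _pad_input(x: np.ndarray, padding: int) -> np.ndarray:
    if padding == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*kh*kw, L) column matrix of receptive fields."""
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, oh, ow = windows.shape[:4]
    cols = windows.reshape(b, c, oh * ow, kh * kw)
    cols = cols.transpose(0, 1, 3, 2).reshape(b, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, padding: int) -> np.ndarray:
    """Fold (B, C*kh*kw, L) column gradients back onto the padded input."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(b, c, kh * kw, oh, ow)
    out = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for idx in range(kh * kw):
        di, dj = divmod(idx, kw)
        out[:, :, di : di + stride * oh : stride, dj : dj + stride * ow : stride] += cols[:, :, idx]
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of a (B, C, H, W) batch with an (O, C, kh, kw) kernel."""
    if x.ndim != 4:
        raise ValueError(f"conv2d expects a 4-D batch, got shape {x.shape}")
    o, c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"conv2d channel mismatch: input has {x.shape[1]}, kernel expects {c}")
    xp = _pad_input(x.data, padding)
    cols, (oh, ow) = _im2col(xp, kh, kw, stride)
    wmat = weight.data.reshape(o, -1)
    out = np.einsum("ok,bkl->bol", wmat, cols, optimize=True)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1)
    out = out.reshape(x.shape[0], o, oh, ow)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(g.shape[0], o, -1)
        gw = np.einsum("bol,bkl->ok", gmat, cols, optimize=True).reshape(weight.shape)
        gcols = np.einsum("ok,bol->bkl", wmat, gmat, optimize=True)
        gx = _col2im(gcols, x.shape, kh, kw, stride, padding)
        grads = [(x, gx.astype(DEFAULT_DTYPE)), (weight, gw.astype(DEFAULT_DTYPE))]
        if bias is not None:
            grads.append((bias, gmat.sum(axis=(0, 2)).astype(DEFAULT_DTYPE)))
        return tuple(grads)

    return Tensor._make(out.astype(DEFAULT_DTYPE), parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling with overlapping windows; backward scatters to argmax cells."""
    b, c, h, w = x.shape
    xp = _pad_input(x.data, padding)
    if padding:
        xp = xp.copy()
        # padded cells must never win the max
        mask = np.zeros_like(xp, dtype=bool)
        mask[:, :, padding:-padding, padding:-padding] = True
        xp[~mask] = -np.inf
    cols, (oh, ow) = _im2col(xp, kernel, kernel, stride)
    cols = cols.reshape(b, c, kernel * kernel, oh * ow)
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :].reshape(b, c, oh, ow)

    def backward(g):
        gcols = np.zeros((b, c, kernel * kernel, oh * ow), dtype=DEFAULT_DTYPE)
        np.put_along_axis(gcols, arg[:, :, None, :], g.reshape(b, c, 1, oh * ow), axis=2)
        gx = _col2im(gcols.reshape(b, c * kernel * kernel, oh * ow), x.shape, kernel, kernel, stride, padding)
        return ((x, gx.astype(DEFAULT_DTYPE)),)

    return Tensor._make(out.astype(DEFAULT_DTYPE), (x,), backward)


def global_avg_pool2d(x: Tensor) -> Tensor:
    """Adaptive average pooling to 1x1 output: the spatial mean per channel."""
    return x.mean(axis=(2, 3))
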