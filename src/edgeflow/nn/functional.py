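"""Differentiable array operations: convolution, pooling, resampling, softmax."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .tensor import Array, Tensor, as_tensor


def _pair(v) -> Tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


def _window_view(xp: Array, kh: int, kw: int, sh: int, sw: int) -> Array:
    """Strided (B, C, Ho, Wo, kh, kw) view of a padded (B, C, H, W) array."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    kh, kw = weight.shape[2], weight.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _window_view(xp, kh, kw, sh, sw)  # (B, C, Ho, Wo, kh, kw)
    val = np.einsum("bchwij,ocij->bohw", cols, weight.data, optimize=True)
    if bias is not None:
        val = val + bias.data[None, :, None, None]
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(val, requires_grad=any(p.requires_grad for p in parents), _parents=parents)

    def bw(g: Array) -> None:
        if weight.requires_grad:
            weight._accumulate(np.einsum("bchwij,bohw->ocij", cols, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            Ho, Wo = g.shape[2], g.shape[3]
            for i in range(kh):
                for j in range(kw):
                    patch = np.einsum("bohw,oc->bchw", g, weight.data[:, :, i, j], optimize=True)
                    gx[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += patch
            H, W = x.shape[2], x.shape[3]
            x._accumulate(gx[:, :, ph : ph + H, pw : pw + W])

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, kernel: int, stride: Optional[int] = None, padding: int = 0) -> Tensor:
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    ph, pw = _pair(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = _window_view(xp, kh, kw, sh, sw)
    val = win.mean(axis=(4, 5))
    out = Tensor(val, requires_grad=x.requires_grad, _parents=(x,))

    def bw(g: Array) -> None:
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        Ho, Wo = g.shape[2], g.shape[3]
        gk = g / float(kh * kw)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += gk
        H, W = x.shape[2], x.shape[3]
        x._accumulate(gx[:, :, ph : ph + H, pw : pw + W])

    out._backward = bw
    return out


def max_pool2d_array(x: Array, kernel: int, stride: int, padding: int = 0) -> Array:
    """Forward-only max pool on a plain array (frozen backbone path)."""
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf)
    return _window_view(xp, kh, kw, sh, sw).max(axis=(4, 5))


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    f = int(factor)
    val = x.data.repeat(f, axis=2).repeat(f, axis=3)
    out = Tensor(val, requires_grad=x.requires_grad, _parents=(x,))

    def bw(g: Array) -> None:
        if x.requires_grad:
            B, C, H, W = x.shape
            x._accumulate(g.reshape(B, C, H, f, W, f).sum(axis=(3, 5)))

    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) mean over space."""
    return x.mean(axis=(2, 3), keepdims=True)


def softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()
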