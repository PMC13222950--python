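"""Fused array operations for the autograd engine.

These are written as single graph nodes (rather than compositions of
elementary ops) where the composed form would be slow or memory-hungry:
convolution via im2col, window pooling, nearest upsampling, layer
normalization, softmax and bilinear point sampling.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, add_macs

__all__ = [
    "conv2d",
    "avg_pool2d",
    "max_pool2d",
    "upsample_nearest2d",
    "adaptive_avg_pool2d",
    "layer_norm",
    "softmax",
    "log_softmax",
    "dropout",
    "bilinear_sample",
]


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation.  ``x``: (B,Cin,H,W); ``w``: (Cout,Cin/G,kh,kw)."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    G = groups
    if Cin != Cin_g * G:
        raise ValueError(f"conv2d: {Cin} input channels, weight expects {Cin_g * G}")
    if Cout % G:
        raise ValueError("conv2d: out_channels must divide by groups")
    s, p = stride, padding

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1

    # windows: (B, Cin, Ho, Wo, kh, kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # -> (G, B*Ho*Wo, Cin_g*kh*kw)
    cols = np.ascontiguousarray(
        win.reshape(B, G, Cin_g, Ho, Wo, kh, kw).transpose(1, 0, 3, 4, 2, 5, 6)
    ).reshape(G, B * Ho * Wo, Cin_g * kh * kw)
    wmat = w.data.reshape(G, Cout // G, Cin_g * kh * kw)

    out = cols @ wmat.transpose(0, 2, 1)  # (G, B*Ho*Wo, Cout/G)
    add_macs(B * Ho * Wo * Cout * Cin_g * kh * kw)
    out = out.reshape(G, B, Ho, Wo, Cout // G).transpose(1, 0, 4, 2, 3)
    out = np.ascontiguousarray(out).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    def backward(g):
        gout = g.reshape(B, G, Cout // G, Ho, Wo).transpose(1, 0, 3, 4, 2)
        gout = np.ascontiguousarray(gout).reshape(G, B * Ho * Wo, Cout // G)
        if w.requires_grad or w._prev:
            gw = np.swapaxes(gout, 1, 2) @ cols  # (G, Cout/G, K)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._prev):
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gcols = gout @ wmat  # (G, B*Ho*Wo, K)
            gcols = gcols.reshape(G, B, Ho, Wo, Cin_g, kh, kw)
            gxp = np.zeros((B, Cin, Hp, Wp), dtype=x.data.dtype)
            gxp_g = gxp.reshape(B, G, Cin_g, Hp, Wp)
            for i in range(kh):
                for j in range(kw):
                    gxp_g[:, :, :, i : i + s * Ho : s, j : j + s * Wo : s] += (
                        gcols[:, :, :, :, :, i, j].transpose(1, 0, 4, 2, 3)
                    )
            x._accum(gxp[:, :, p : Hp - p, p : Wp - p] if p else gxp)

    prev = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, prev, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k×k average pooling (kernel = stride = k)."""
    B, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial dims {(H, W)} not divisible by {k}")
    out = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (k * k), (B, C, H // k, k, W // k, k)
        )
        x._accum(gx.reshape(B, C, H, W))

    return Tensor._make(out, (x,), backward)


def max_pool2d(x: Tensor, k: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.shape
    p, s = padding, stride
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        if p
        else x.data
    )
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // s + 1
    Wo = (Wp - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros((B, C, Hp, Wp), dtype=x.data.dtype)
        bi, ci, hi, wi = np.indices((B, C, Ho, Wo))
        rows = hi * s + idx // k
        cols = wi * s + idx % k
        np.add.at(gxp, (bi, ci, rows, cols), g)
        x._accum(gxp[:, :, p : Hp - p, p : Wp - p] if p else gxp)

    return Tensor._make(out, (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    B, C, H, W = x.shape
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        gx = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


def adaptive_avg_pool2d(x: Tensor) -> Tensor:
    """Global average pool to 1×1."""
    return x.mean(axis=(2, 3), keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad or gamma._prev:
            gamma._accum(
                (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
            )
        if beta.requires_grad or beta._prev:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad or x._prev:
            gh = g * gamma.data
            gx = (
                gh
                - gh.mean(axis=-1, keepdims=True)
                - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accum(gx)

    return Tensor._make(out, (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accum(out * (g - dot))

    return Tensor._make(out, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    sm = np.exp(out)

    def backward(g):
        x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out, (x,), backward)


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = x.data * mask

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(out, (x,), backward)


def bilinear_sample(value: Tensor, locs: Tensor) -> Tensor:
    """Sample ``value`` (B,C,H,W) at continuous pixel locations.

    ``locs``: (B,P,2) with (x,y) in pixel coordinates of the value grid
    (0..W-1, 0..H-1).  Out-of-range locations are clamped to the border,
    matching aligned-corner bilinear interpolation.  Returns (B,C,P).
    Gradients flow to both the value map and the locations.
    """
    B, C, H, W = value.shape
    P = locs.shape[1]
    xf = np.clip(locs.data[..., 0], 0.0, W - 1.0)
    yf = np.clip(locs.data[..., 1], 0.0, H - 1.0)
    x0 = np.floor(xf).astype(np.int64)
    y0 = np.floor(yf).astype(np.int64)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    tx = (xf - x0).astype(value.data.dtype)
    ty = (yf - y0).astype(value.data.dtype)

    bi = np.arange(B)[:, None]
    v = value.data
    v00 = v[bi, :, y0, x0]  # (B,P,C)
    v01 = v[bi, :, y0, x1]
    v10 = v[bi, :, y1, x0]
    v11 = v[bi, :, y1, x1]
    txe = tx[..., None]
    tye = ty[..., None]
    top = v00 * (1 - txe) + v01 * txe
    bot = v10 * (1 - txe) + v11 * txe
    out = (top * (1 - tye) + bot * tye).transpose(0, 2, 1)  # (B,C,P)
    add_macs(B * C * P * 8)

    # gradient of clamping: zero outside the valid range
    in_x = ((locs.data[..., 0] > 0.0) & (locs.data[..., 0] < W - 1.0)).astype(
        value.data.dtype
    )
    in_y = ((locs.data[..., 1] > 0.0) & (locs.data[..., 1] < H - 1.0)).astype(
        value.data.dtype
    )

    def backward(g):
        gp = g.transpose(0, 2, 1)  # (B,P,C)
        if value.requires_grad or value._prev:
            gv = np.zeros_like(v)
            w00 = ((1 - txe) * (1 - tye)) * gp
            w01 = (txe * (1 - tye)) * gp
            w10 = ((1 - txe) * tye) * gp
            w11 = (txe * tye) * gp
            np.add.at(gv, (bi, slice(None), y0, x0), w00)
            np.add.at(gv, (bi, slice(None), y0, x1), w01)
            np.add.at(gv, (bi, slice(None), y1, x0), w10)
            np.add.at(gv, (bi, slice(None), y1, x1), w11)
            value._accum(gv)
        if locs.requires_grad or locs._prev:
            dx = ((v01 - v00) * (1 - tye) + (v11 - v10) * tye) * gp
            dy = (bot - top) * gp
            gl = np.stack(
                [dx.sum(axis=-1) * in_x, dy.sum(axis=-1) * in_y], axis=-1
            )
            locs._accum(gl)

    return Tensor._make(out, (value, locs), backward)
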