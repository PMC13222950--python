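"""HSATE: hybrid-encoder block built around polarized linear attention.

The detection transformer applies self-attention only to the flattened
stride-32 feature map.  The baseline block (:class:`AIFI`) is a standard
post-norm transformer encoder layer with softmax attention and an FFN.
:class:`HSATEBlock` replaces it with

* polarized linear attention (PLA): the softmax kernel is replaced by
  ``phi(x) = relu(x)**alpha`` applied separately to the positive and
  negative parts of the queries/keys.  The key–value product is pooled
  into a d×d summary first, so no N×N attention matrix is ever formed
  and cost is linear in the token count;
* a parallel spatial enhancement network (PSEN) in place of the FFN,
  which adds a pooled-and-restored spatial context branch and a learned
  gate;
* two multi-scale adaptive enhancement modules (MAEM) with parallel
  depthwise 3/5/7 branches, placed after each residual+norm step.

Token sequences are (B, N, C) with an attached (H, W) grid shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "TokenSequence",
    "PLAParams",
    "MAEMParams",
    "kernel_phi",
    "softmax_attention",
    "pla_attention",
    "MultiheadAttention",
    "PolarizedLinearAttention",
    "PSEN",
    "MAEMOp",
    "MAEM",
    "HSATEBlock",
    "AIFI",
    "sine_position_embedding",
]


@dataclass
class TokenSequence:
    """Flattened spatial tokens: ``data`` is (B, N, C) with N = H*W."""

    data: Tensor
    spatial_shape: tuple[int, int]

    def __post_init__(self):
        H, W = self.spatial_shape
        if self.data.shape[1] != H * W:
            raise ValueError(
                f"token count {self.data.shape[1]} != H*W = {H * W}"
            )


@dataclass
class PLAParams:
    alpha: float = 1.0
    head_dim: int = 32
    num_heads: int = 8
    eps: float = 1e-6

    def __post_init__(self):
        alpha = float(self.alpha.data) if isinstance(self.alpha, Tensor) else self.alpha
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.head_dim < 1:
            raise ValueError("head_dim must be >= 1")


@dataclass
class MAEMParams:
    channels: int = 256
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    dropout_rate: float = 0.1

    def __post_init__(self):
        if set(self.kernel_sizes) != {3, 5, 7}:
            raise ValueError("kernel sizes must be exactly {3, 5, 7}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


def kernel_phi(x, alpha):
    """Kernel feature map ``phi(x) = relu(x) ** alpha``; nonnegative output."""
    alpha_val = float(alpha.data) if isinstance(alpha, Tensor) else float(alpha)
    if alpha_val <= 0:
        raise ValueError("kernel_phi: alpha must be positive")
    if isinstance(x, Tensor):
        if isinstance(alpha, Tensor):
            return x.relu().pow_elementwise(alpha)
        return x.relu().pow_elementwise(Tensor(np.asarray(alpha)))
    return np.maximum(x, 0.0) ** alpha_val


def softmax_attention(Q: Tensor, K: Tensor, V: Tensor, d_k: int) -> Tensor:
    """Scaled dot-product attention — the quadratic reference form.

    Shapes (..., N, d); the attention matrix rows sum to one.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    scores = Q.matmul(K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2))
    attn = F.softmax(scores * (1.0 / np.sqrt(d_k)), axis=-1)
    return attn.matmul(V)


def pla_attention(Q, K, V, params: PLAParams) -> Tensor:
    """Polarized linear attention over (..., N, d) slices.

    Both queries and keys are split into positive and negative parts
    (``relu(x)`` and ``relu(-x)``); each polarity is kernelized with
    ``phi = relu(.)**alpha``, contracted against the pooled d×d key–value
    summary, normalized by the pooled kernelized-key mass, and the two
    polarity terms are combined with opposite signs.  Cost is O(N·d²):
    no N×N matrix is ever materialized.
    """
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    alpha = params.alpha if isinstance(params.alpha, Tensor) else float(params.alpha)
    N = K.shape[-2]
    inv_n = 1.0 / float(N)

    def polarity(sign: float):
        phi_q = kernel_phi(Q * sign, alpha)
        phi_k = kernel_phi(K * sign, alpha)
        # pooled key-value summary, d×d: (1/N) * phi(K)^T V
        kt = phi_k.transpose(*range(phi_k.ndim - 2), phi_k.ndim - 1, phi_k.ndim - 2)
        kv = kt.matmul(V) * inv_n
        num = phi_q.matmul(kv)  # (..., N, d)
        kmass = phi_k.mean(axis=-2, keepdims=True)  # (..., 1, d)
        den = (phi_q * kmass).sum(axis=-1, keepdims=True) + params.eps
        return num / den

    return polarity(1.0) - polarity(-1.0)


class MultiheadAttention(nn.Module):
    """Standard softmax multi-head attention (used by AIFI and the decoder)."""

    def __init__(self, embed_dim: int, num_heads: int):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError("embed_dim must divide by num_heads")
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.head_dim = embed_dim // num_heads
        self.q_proj = nn.Linear(embed_dim, embed_dim)
        self.k_proj = nn.Linear(embed_dim, embed_dim)
        self.v_proj = nn.Linear(embed_dim, embed_dim)
        self.out_proj = nn.Linear(embed_dim, embed_dim)

    def _split(self, x: Tensor) -> Tensor:
        B, N, _ = x.shape
        return x.reshape(B, N, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        B, N, _ = q.shape
        qh = self._split(self.q_proj(q))
        kh = self._split(self.k_proj(k))
        vh = self._split(self.v_proj(v))
        out = softmax_attention(qh, kh, vh, self.head_dim)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, self.embed_dim)
        return self.out_proj(out)


class PolarizedLinearAttention(nn.Module):
    """Multi-head PLA with q/k/v/out projections and a learnable kernel
    power alpha (clamped to [0.5, 3])."""

    def __init__(self, embed_dim: int, num_heads: int = 8, alpha_init: float = 1.0):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError("embed_dim must divide by num_heads")
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.head_dim = embed_dim // num_heads
        self.q_proj = nn.Linear(embed_dim, embed_dim)
        self.k_proj = nn.Linear(embed_dim, embed_dim)
        self.v_proj = nn.Linear(embed_dim, embed_dim)
        self.out_proj = nn.Linear(embed_dim, embed_dim)
        self.alpha = nn.Parameter(np.array(alpha_init, dtype=np.float32))
        self.eps = 1e-6

    def forward(self, x: Tensor) -> Tensor:
        B, N, _ = x.shape
        h, dh = self.num_heads, self.head_dim
        q = self.q_proj(x).reshape(B, N, h, dh).transpose(0, 2, 1, 3)
        k = self.k_proj(x).reshape(B, N, h, dh).transpose(0, 2, 1, 3)
        v = self.v_proj(x).reshape(B, N, h, dh).transpose(0, 2, 1, 3)
        params = PLAParams(
            alpha=self.alpha.clamp(0.5, 3.0), head_dim=dh, num_heads=h, eps=self.eps
        )
        out = pla_attention(q, k, v, params)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, self.embed_dim)
        return self.out_proj(out)


def _tokens_to_grid(x: Tensor, shape: tuple[int, int]) -> Tensor:
    B, N, C = x.shape
    H, W = shape
    return x.transpose(0, 2, 1).reshape(B, C, H, W)


def _grid_to_tokens(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    return x.reshape(B, C, H * W).transpose(0, 2, 1)


class PSEN(nn.Module):
    """Parallel spatial enhancement network — the FFN replacement.

    The input (plus the block's skip tokens) is expanded by a 1×1 conv
    whose output splits into a fusion half F1 and a gating half F2.  A
    spatial branch average-pools the input by 2, runs a two-conv sequence
    with GELU, and restores resolution by nearest upsampling.  The fused
    [spatial, F1] stack passes through 1×1 fusion, depthwise 3×3 and a
    final 1×1, and is gated elementwise by sigmoid(F2).
    """

    def __init__(self, channels: int, pool_stride: int = 2):
        super().__init__()
        c = channels
        self.pool_stride = pool_stride
        self.expand = nn.Conv2d(c, 2 * c, 1)
        self.convseq = nn.Sequential(
            nn.Conv2d(c, c, 3, padding=1), nn.GELU(), nn.Conv2d(c, c, 3, padding=1)
        )
        self.fusion = nn.Conv2d(2 * c, c, 1)
        self.dw = nn.Conv2d(c, c, 3, padding=1, groups=c)
        self.out_conv = nn.Conv2d(c, c, 1)

    def forward(self, x: TokenSequence, skip: TokenSequence) -> TokenSequence:
        if x.spatial_shape is None:
            raise ValueError("PSEN requires a spatial shape")
        H, W = x.spatial_shape
        g = _tokens_to_grid(x.data + skip.data, (H, W))
        s = self.pool_stride
        pad_h = (-H) % s
        pad_w = (-W) % s
        g_in = _pad_bottom_right(g, pad_h, pad_w) if (pad_h or pad_w) else g
        expanded = self.expand(g_in)
        c = g.shape[1]
        f1 = expanded[:, :c]
        f2 = expanded[:, c:]
        spatial = F.avg_pool2d(g_in, s)
        spatial = self.convseq(spatial)
        spatial = F.upsample_nearest2d(spatial, s)
        fused = self.fusion(concat([spatial, f1], axis=1))
        fused = self.out_conv(self.dw(fused).gelu())
        gated = fused * f2.sigmoid()
        if pad_h or pad_w:
            gated = gated[:, :, :H, :W]
        return TokenSequence(_grid_to_tokens(gated), (H, W))


def _pad_bottom_right(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    width = [(0, 0), (0, 0), (0, pad_h), (0, pad_w)]
    out_data = np.pad(x.data, width)
    sl = (slice(None), slice(None), slice(0, x.shape[2]), slice(0, x.shape[3]))

    def backward(g):
        x._accum(g[sl])

    return Tensor._make(out_data, (x,), backward)


class MAEMOp(nn.Module):
    """Three-branch depthwise enhancement:
    ``X + (1/3) * sum_k DWConv_k(X + Conv1x1(X))`` for k in {3, 5, 7}."""

    def __init__(self, channels: int):
        super().__init__()
        self.pre = nn.Conv2d(channels, channels, 1)
        self.dw3 = nn.Conv2d(channels, channels, 3, padding=1, groups=channels)
        self.dw5 = nn.Conv2d(channels, channels, 5, padding=2, groups=channels)
        self.dw7 = nn.Conv2d(channels, channels, 7, padding=3, groups=channels)

    def forward(self, x: Tensor) -> Tensor:
        inner = x + self.pre(x)
        branches = self.dw3(inner) + self.dw5(inner) + self.dw7(inner)
        return x + branches * (1.0 / 3.0)


class MAEM(nn.Module):
    """Multi-scale adaptive enhancement on token sequences.

    ``X + Conv1x1(Dropout(GELU(MAEMOp(Conv1x1(X*gamma + LN(X)*gamma_x)))))``
    with learnable per-channel scaling gamma (init 1) and mixing gamma_x
    (init 0).
    """

    def __init__(self, channels: int, dropout: float = 0.1):
        super().__init__()
        self.channels = channels
        self.gamma = nn.Parameter(np.ones(channels, dtype=np.float32))
        self.gamma_x = nn.Parameter(np.zeros(channels, dtype=np.float32))
        self.norm = nn.LayerNorm(channels)
        self.conv_in = nn.Conv2d(channels, channels, 1)
        self.op = MAEMOp(channels)
        self.conv_out = nn.Conv2d(channels, channels, 1)
        self.drop = nn.Dropout(dropout)

    def forward(self, x: TokenSequence) -> TokenSequence:
        if x.spatial_shape is None:
            raise ValueError("MAEM requires a spatial shape")
        t = x.data
        mixed = t * self.gamma + self.norm(t) * self.gamma_x
        g = _tokens_to_grid(mixed, x.spatial_shape)
        y = self.conv_out(self.drop(self.op(self.conv_in(g)).gelu()))
        return TokenSequence(t + _grid_to_tokens(y), x.spatial_shape)


class HSATEBlock(nn.Module):
    """The full encoder block:

    ``Z_attn = MAEM1(LN(X + Dropout(PLA(X))))``
    ``Z_out  = MAEM2(LN(Z_attn + Dropout(PSEN(Z_attn, X))))``
    """

    def __init__(
        self,
        embed_dim: int = 256,
        num_heads: int = 8,
        alpha_init: float = 1.0,
        maem_dropout: float = 0.1,
        block_dropout: float = 0.0,
        psen_pool_stride: int = 2,
    ):
        super().__init__()
        self.attn = PolarizedLinearAttention(embed_dim, num_heads, alpha_init)
        self.drop1 = nn.Dropout(block_dropout)
        self.norm1 = nn.LayerNorm(embed_dim)
        self.maem1 = MAEM(embed_dim, maem_dropout)
        self.psen = PSEN(embed_dim, psen_pool_stride)
        self.drop2 = nn.Dropout(block_dropout)
        self.norm2 = nn.LayerNorm(embed_dim)
        self.maem2 = MAEM(embed_dim, maem_dropout)

    def forward(self, x: TokenSequence) -> TokenSequence:
        t = x.data
        z = self.norm1(t + self.drop1(self.attn(t)))
        z_attn = self.maem1(TokenSequence(z, x.spatial_shape))
        p = self.psen(z_attn, x)
        z2 = self.norm2(z_attn.data + self.drop2(p.data))
        return self.maem2(TokenSequence(z2, x.spatial_shape))


class AIFI(nn.Module):
    """Baseline intra-scale interaction: post-norm transformer encoder
    layer (softmax MHA + FFN) on the stride-32 tokens."""

    def __init__(
        self,
        embed_dim: int = 256,
        num_heads: int = 8,
        ffn_dim: int = 1024,
        dropout: float = 0.0,
    ):
        super().__init__()
        self.attn = MultiheadAttention(embed_dim, num_heads)
        self.norm1 = nn.LayerNorm(embed_dim)
        self.linear1 = nn.Linear(embed_dim, ffn_dim)
        self.linear2 = nn.Linear(ffn_dim, embed_dim)
        self.norm2 = nn.LayerNorm(embed_dim)
        self.drop = nn.Dropout(dropout)

    def forward(self, x: TokenSequence) -> TokenSequence:
        t = x.data
        a = self.attn(t, t, t)
        t = self.norm1(t + self.drop(a))
        f = self.linear2(self.drop(self.linear1(t).gelu()))
        t = self.norm2(t + self.drop(f))
        return TokenSequence(t, x.spatial_shape)


def sine_position_embedding(h: int, w: int, dim: int, temperature: float = 10000.0):
    """2-D sine/cosine positional encoding, (1, h*w, dim) numpy array."""
    if dim % 4:
        raise ValueError("embed dim must divide by 4 for 2-D sine embedding")
    gw, gh = np.meshgrid(np.arange(w, dtype=np.float32), np.arange(h, dtype=np.float32))
    pos_dim = dim // 4
    omega = 1.0 / temperature ** (np.arange(pos_dim, dtype=np.float32) / pos_dim)
    out_w = gw.flatten()[:, None] * omega[None]
    out_h = gh.flatten()[:, None] * omega[None]
    emb = np.concatenate(
        [np.sin(out_w), np.cos(out_w), np.sin(out_h), np.cos(out_h)], axis=1
    )
    return emb[None].astype(np.float32)
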