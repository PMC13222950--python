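"""ESCU: efficient spatial-channel upsampling.

A lightweight ×2 upsampler used at the pyramid-fusion upsample sites:
nearest-neighbour interpolation, a depthwise-separable convolution,
grouped channel shuffle and a four-way circular spatial shift.  The two
mixing operations are parameter-free permutations/rolls; all learnable
cost sits in the depthwise 3×3 + pointwise 1×1 pair, which keeps the
block far cheaper than a transposed convolution at equal width.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "ESCUConfig",
    "channel_shuffle",
    "spatial_shift_mix",
    "DepthwiseSeparableConv",
    "ESCU",
]


@dataclass
class ESCUConfig:
    channels: int
    groups: int = 4
    shift_step: int = 1
    activation: str = "silu"

    def __post_init__(self):
        if self.channels % self.groups:
            raise ValueError("channels must divide by groups")
        if self.channels % 4:
            raise ValueError("channels must divide by 4 (four shift subsets)")
        if self.shift_step < 0:
            raise ValueError("shift step must be non-negative")


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Grouped channel permutation via reshape–transpose–reshape.

    Channels are viewed as ``(G, C/G)``, the two axes are swapped, and the
    result is flattened back — a fixed bijective permutation that moves one
    channel from every group into each contiguous block of the output.
    """
    B, C, H, W = x.shape
    if C % groups:
        raise ValueError(f"channel_shuffle: {C} channels not divisible by G={groups}")
    g = x.reshape(B, groups, C // groups, H, W)
    t = g.transpose(0, 2, 1, 3, 4)
    return t.reshape(B, C, H, W)


def spatial_shift_mix(x: Tensor, s: int) -> Tensor:
    """Circular ±s shifts of four channel quarters along height/width.

    Quarters 1–2 roll by +s/−s along the height axis, quarters 3–4 by
    +s/−s along the width axis.  Rolls are circular, so every per-channel
    spatial sum is conserved exactly and ``s -> -s`` inverts the op.
    """
    C = x.shape[1]
    if C % 4:
        raise ValueError(f"spatial_shift_mix: {C} channels not divisible by 4")
    q = C // 4
    parts = [
        x[:, 0 * q : 1 * q].roll(s, axis=2),
        x[:, 1 * q : 2 * q].roll(-s, axis=2),
        x[:, 2 * q : 3 * q].roll(s, axis=3),
        x[:, 3 * q : 4 * q].roll(-s, axis=3),
    ]
    return concat(parts, axis=1)


_ACTS = {"silu": nn.SiLU, "relu": nn.ReLU, "gelu": nn.GELU, "identity": nn.Identity}


class DepthwiseSeparableConv(nn.Module):
    """Depthwise 3×3 followed by pointwise 1×1, with BN + activation."""

    def __init__(self, channels: int, activation: str = "silu"):
        super().__init__()
        self.dw = nn.Conv2d(channels, channels, 3, padding=1, groups=channels, bias=False)
        self.pw = nn.Conv2d(channels, channels, 1, bias=False)
        self.bn = nn.BatchNorm2d(channels)
        self.act = _ACTS[activation]()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.pw(self.dw(x))))


class ESCU(nn.Module):
    """×2 upsampler: NN-interpolate → depthwise-separable conv → channel
    shuffle → spatial shift mix."""

    def __init__(self, cfg: ESCUConfig):
        super().__init__()
        self.cfg = cfg
        self.conv = DepthwiseSeparableConv(cfg.channels, cfg.activation)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"ESCU configured for {self.cfg.channels} channels, got {x.shape[1]}"
            )
        y = F.upsample_nearest2d(x, 2)
        y = self.conv(y)
        y = channel_shuffle(y, self.cfg.groups)
        return spatial_shift_mix(y, self.cfg.shift_step)
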