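"""DASPMNet: a CSP-style backbone with prompt-guided self-attention blocks.

The backbone replaces ResNet-18 in the detector.  Its building block,
the adaptive feature enhancement block (AFEB), projects the input with a
1×1 conv, splits the channels into two halves, runs a cascade of
self-attention blocks (SAB) on one half while the other passes through
untouched, concatenates the untouched half with the output of every SAB
in the cascade, and recombines with a terminal 1×1 conv — the cross-stage
partial topology, with attention in place of plain convolutions.

Each SAB wraps a prompt-guided attention operator: a learnable prompt
vector is projected to the block width, broadcast over the spatial grid
and fused with the features by a 1×1 conv to produce per-position
attention logits; softmax over the spatial positions turns these into an
attention map that weights a 3×3 value path, which is aggregated into a
global context vector, transformed, and added back residually.  With the
attention map forced uniform the block therefore adds exactly the
spatially averaged (transformed) value path; with zeroed value/transform
weights it is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "FeatureMap",
    "AFEBConfig",
    "PyramidFeatures",
    "DASPMNetConfig",
    "split_channels",
    "SAEPGO",
    "SAB",
    "AFEB",
    "ConvBNAct",
    "DASPMNet",
]


@dataclass
class FeatureMap:
    """A (B, C, H, W) activation with its downsampling stride."""

    data: Tensor
    stride: int

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("FeatureMap must be 4-D (B, C, H, W)")
        if not np.all(np.isfinite(self.data.data)):
            raise ValueError("FeatureMap contains non-finite values")


@dataclass
class AFEBConfig:
    in_channels: int
    out_channels: int
    num_sab: int = 1
    prompt_dim: int = 32
    hidden_channels: int | None = None  # width after the 1x1 projection

    def __post_init__(self):
        hidden = self.hidden_channels or self.in_channels
        if hidden % 2:
            raise ValueError("hidden channel count must be even to split in half")
        if self.num_sab < 1:
            raise ValueError("num_sab must be >= 1")
        self.hidden_channels = hidden


@dataclass
class PyramidFeatures:
    """Exactly three pyramid levels at strides 8, 16, 32."""

    levels: tuple[FeatureMap, FeatureMap, FeatureMap]

    def __post_init__(self):
        if len(self.levels) != 3:
            raise ValueError("pyramid must have exactly 3 levels")
        if tuple(l.stride for l in self.levels) != (8, 16, 32):
            raise ValueError("pyramid strides must be (8, 16, 32)")


def split_channels(x: Tensor) -> tuple[Tensor, Tensor]:
    """Split a (B, C, H, W) map into two C/2 halves along channels."""
    C = x.shape[1]
    if C % 2:
        raise ValueError(f"split_channels: odd channel count {C}")
    return x[:, : C // 2], x[:, C // 2 :]


class ConvBNAct(nn.Module):
    def __init__(self, cin, cout, k=1, stride=1, act=True, groups=1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2,
                              groups=groups, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class SAEPGO(nn.Module):
    """Prompt-guided global-context attention operator.

    attention logits = Conv1x1([x ; broadcast(W_p p)]); softmax over the
    spatial grid; context = sum_s A(s) * V(s) with V a (grouped) 3×3 value
    conv; output = x + Conv1x1(context) broadcast back over space.
    """

    def __init__(self, channels: int, prompt_dim: int = 32, value_groups: int = 1):
        super().__init__()
        self.channels = channels
        self.prompt = nn.Parameter(
            nn.get_rng().normal(0.0, 0.02, prompt_dim).astype(np.float32)
        )
        self.prompt_proj = nn.Linear(prompt_dim, channels)
        # no bias: the spatial softmax is invariant to a uniform logit shift
        self.attn_conv = nn.Conv2d(2 * channels, 1, 1, bias=False)
        self.value = nn.Conv2d(channels, channels, 3, padding=1, groups=value_groups)
        self.transform = nn.Conv2d(channels, channels, 1)

    def attention_map(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        p = self.prompt_proj(self.prompt.reshape(1, -1))  # (1, C)
        pmap = p.reshape(1, C, 1, 1) * Tensor(np.ones((B, C, H, W), dtype=np.float32))
        logits = self.attn_conv(concat([x, pmap], axis=1))  # (B,1,H,W)
        flat = logits.reshape(B, 1, H * W)
        return F.softmax(flat, axis=-1).reshape(B, 1, H, W)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        attn = self.attention_map(x)
        v = self.value(x)
        context = (v * attn).sum(axis=(2, 3), keepdims=True)  # (B,C,1,1)
        return x + self.transform(context)


class SAB(nn.Module):
    """Self-attention block: SAEPGO with its built-in residual path."""

    def __init__(self, channels: int, prompt_dim: int = 32, value_groups: int = 1):
        super().__init__()
        self.op = SAEPGO(channels, prompt_dim, value_groups)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.op.channels:
            raise ValueError(
                f"SAB configured for {self.op.channels} channels, got {x.shape[1]}"
            )
        return self.op(x)


class AFEB(nn.Module):
    """Adaptive feature enhancement block (CSP split + SAB cascade)."""

    def __init__(self, cfg: AFEBConfig, value_groups: int = 1):
        super().__init__()
        self.cfg = cfg
        hidden = cfg.hidden_channels
        half = hidden // 2
        self.proj = ConvBNAct(cfg.in_channels, hidden, 1)
        self.sabs = nn.ModuleList(
            SAB(half, cfg.prompt_dim, value_groups) for _ in range(cfg.num_sab)
        )
        concat_width = (cfg.num_sab + 1) * half
        self.terminal = ConvBNAct(concat_width, cfg.out_channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"AFEB expects {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        f1, f2 = split_channels(self.proj(x))
        feats = [f1]
        cur = f2
        for sab in self.sabs:
            cur = sab(cur)
            feats.append(cur)
        return self.terminal(concat(feats, axis=1))


@dataclass
class DASPMNetConfig:
    stem_channels: int = 64
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    num_sab: tuple[int, int, int, int] = (1, 2, 3, 3)
    prompt_dim: int = 32
    value_groups: tuple[int, int, int, int] = (1, 1, 1, 1)

    @staticmethod
    def from_dict(d: dict) -> "DASPMNetConfig":
        cfg = DASPMNetConfig()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown DASPMNet config key {k}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg


class DASPMNet(nn.Module):
    """Four-stage backbone: deep stem (stride 4) + AFEB stage, then three
    (strided conv + AFEB) stages emitting the stride-8/16/32 pyramid."""

    def __init__(self, cfg: DASPMNetConfig | None = None):
        super().__init__()
        cfg = cfg or DASPMNetConfig()
        self.cfg = cfg
        w0, w1, w2, w3 = cfg.stage_widths
        sc = cfg.stem_channels
        self.stem = nn.Sequential(
            ConvBNAct(3, sc // 2, 3, stride=2),
            ConvBNAct(sc // 2, sc // 2, 3),
            ConvBNAct(sc // 2, sc, 3),
            nn.MaxPool2d(3, 2, 1),
        )

        def stage(cin, cout, n, groups, downsample):
            mods = []
            if downsample:
                mods.append(ConvBNAct(cin, cout, 3, stride=2))
                cin = cout
            mods.append(
                AFEB(
                    AFEBConfig(cin, cout, num_sab=n, prompt_dim=cfg.prompt_dim),
                    value_groups=groups,
                )
            )
            return nn.Sequential(*mods)

        self.stage1 = stage(sc, w0, cfg.num_sab[0], cfg.value_groups[0], False)
        self.stage2 = stage(w0, w1, cfg.num_sab[1], cfg.value_groups[1], True)
        self.stage3 = stage(w1, w2, cfg.num_sab[2], cfg.value_groups[2], True)
        self.stage4 = stage(w2, w3, cfg.num_sab[3], cfg.value_groups[3], True)
        self.out_channels = (w1, w2, w3)

    def forward(self, x: Tensor) -> PyramidFeatures:
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ValueError("input spatial dims must divide by 32")
        s1 = self.stage1(self.stem(x))
        s3 = self.stage2(s1)
        s4 = self.stage3(s3)
        s5 = self.stage4(s4)
        return PyramidFeatures(
            (FeatureMap(s3, 8), FeatureMap(s4, 16), FeatureMap(s5, 32))
        )
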