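"""Hybrid encoder: intra-scale attention on the top pyramid level plus
cross-scale CNN fusion (CCFM).

The stride-32 feature map is flattened, given a 2-D sine positional
encoding and passed through either the baseline transformer layer
(:class:`~dsadet.encoder.AIFI`) or the linear-attention replacement
(:class:`~dsadet.encoder.HSATEBlock`).  CCFM then fuses the three levels
with a top-down path (upsample + CSP-style fusion blocks) and a
bottom-up path (strided conv + fusion blocks).  The two ×2 upsample
sites optionally use the ESCU module in place of plain nearest-neighbour
interpolation preceded by a 1×1 lateral conv.
"""

from __future__ import annotations

from . import nn
from .backbone import ConvBNAct, FeatureMap, PyramidFeatures
from .encoder import AIFI, HSATEBlock, TokenSequence, sine_position_embedding
from .nn import functional as F
from .nn.tensor import Tensor, concat
from .upsample import ESCU, ESCUConfig

__all__ = ["RepBlock", "CSPRepLayer", "HybridEncoder"]


class RepBlock(nn.Module):
    """3×3 + 1×1 conv pair summed before the activation."""

    def __init__(self, channels: int):
        super().__init__()
        self.conv3 = ConvBNAct(channels, channels, 3, act=False)
        self.conv1 = ConvBNAct(channels, channels, 1, act=False)
        self.act = nn.SiLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.conv3(x) + self.conv1(x))


class CSPRepLayer(nn.Module):
    def __init__(self, cin: int, cout: int, hidden: int, num_blocks: int = 3):
        super().__init__()
        self.conv1 = ConvBNAct(cin, hidden, 1)
        self.conv2 = ConvBNAct(cin, hidden, 1)
        self.blocks = nn.Sequential(*[RepBlock(hidden) for _ in range(num_blocks)])
        self.conv3 = ConvBNAct(hidden, cout, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv3(self.blocks(self.conv1(x)) + self.conv2(x))


class _LateralUpsample(nn.Module):
    """Baseline upsample site: 1×1 lateral conv then ×2 nearest."""

    def __init__(self, channels: int):
        super().__init__()
        self.lateral = ConvBNAct(channels, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_nearest2d(self.lateral(x), 2)


class HybridEncoder(nn.Module):
    def __init__(
        self,
        in_channels: tuple[int, int, int],
        hidden_dim: int = 256,
        use_hsate: bool = False,
        use_escu: bool = False,
        num_heads: int = 8,
        ffn_dim: int = 1024,
        csp_hidden: int = 128,
        csp_blocks: int = 3,
        alpha_init: float = 1.0,
        maem_dropout: float = 0.1,
        escu_groups: int = 4,
        escu_shift: int = 1,
    ):
        super().__init__()
        self.hidden_dim = hidden_dim
        self.input_proj = nn.ModuleList(
            ConvBNAct(c, hidden_dim, 1, act=False) for c in in_channels
        )
        if use_hsate:
            self.intra = HSATEBlock(
                hidden_dim, num_heads, alpha_init=alpha_init, maem_dropout=maem_dropout
            )
        else:
            self.intra = AIFI(hidden_dim, num_heads, ffn_dim)
        if use_escu:
            mk_up = lambda: ESCU(ESCUConfig(hidden_dim, escu_groups, escu_shift))
        else:
            mk_up = lambda: _LateralUpsample(hidden_dim)
        # top-down: S5 -> S4, then -> S3
        self.up1 = mk_up()
        self.up2 = mk_up()
        self.fpn1 = CSPRepLayer(2 * hidden_dim, hidden_dim, csp_hidden, csp_blocks)
        self.fpn2 = CSPRepLayer(2 * hidden_dim, hidden_dim, csp_hidden, csp_blocks)
        # bottom-up
        self.down1 = ConvBNAct(hidden_dim, hidden_dim, 3, stride=2)
        self.down2 = ConvBNAct(hidden_dim, hidden_dim, 3, stride=2)
        self.pan1 = CSPRepLayer(2 * hidden_dim, hidden_dim, csp_hidden, csp_blocks)
        self.pan2 = CSPRepLayer(2 * hidden_dim, hidden_dim, csp_hidden, csp_blocks)

    def forward(self, pyramid: PyramidFeatures) -> list[FeatureMap]:
        s3, s4, s5 = (
            proj(level.data)
            for proj, level in zip(self.input_proj, pyramid.levels)
        )
        B, C, H5, W5 = s5.shape
        tokens = s5.reshape(B, C, H5 * W5).transpose(0, 2, 1)
        pos = Tensor(sine_position_embedding(H5, W5, C))
        out = self.intra(TokenSequence(tokens + pos, (H5, W5)))
        s5 = out.data.transpose(0, 2, 1).reshape(B, C, H5, W5)

        # top-down
        p4 = self.fpn1(concat([self.up1(s5), s4], axis=1))
        p3 = self.fpn2(concat([self.up2(p4), s3], axis=1))
        # bottom-up
        n4 = self.pan1(concat([self.down1(p3), p4], axis=1))
        n5 = self.pan2(concat([self.down2(n4), s5], axis=1))
        return [FeatureMap(p3, 8), FeatureMap(n4, 16), FeatureMap(n5, 32)]
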