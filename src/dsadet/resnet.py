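"""ResNet-18 backbone for the baseline detector.

Classic form: 7×7 stride-2 stem + max-pool, four stages of two basic
blocks.  Emits the stride-8/16/32 pyramid consumed by the hybrid encoder.
"""

from __future__ import annotations

from . import nn
from .backbone import ConvBNAct, FeatureMap, PyramidFeatures
from .nn.tensor import Tensor

__all__ = ["BasicBlock", "ResNet18"]


class BasicBlock(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int = 1):
        super().__init__()
        self.conv1 = ConvBNAct(cin, cout, 3, stride=stride)
        self.conv2 = ConvBNAct(cout, cout, 3, act=False)
        if stride != 1 or cin != cout:
            self.shortcut = ConvBNAct(cin, cout, 1, stride=stride, act=False)
        else:
            self.shortcut = nn.Identity()
        self.act = nn.SiLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.conv2(self.conv1(x)) + self.shortcut(x))


class ResNet18(nn.Module):
    def __init__(self, widths: tuple[int, int, int, int] = (64, 128, 256, 512)):
        super().__init__()
        w0, w1, w2, w3 = widths
        self.stem = nn.Sequential(
            ConvBNAct(3, w0, 7, stride=2),
            nn.MaxPool2d(3, 2, 1),
        )
        self.layer1 = nn.Sequential(BasicBlock(w0, w0), BasicBlock(w0, w0))
        self.layer2 = nn.Sequential(BasicBlock(w0, w1, 2), BasicBlock(w1, w1))
        self.layer3 = nn.Sequential(BasicBlock(w1, w2, 2), BasicBlock(w2, w2))
        self.layer4 = nn.Sequential(BasicBlock(w2, w3, 2), BasicBlock(w3, w3))
        self.out_channels = (w1, w2, w3)

    def forward(self, x: Tensor) -> PyramidFeatures:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial dims must divide by 32")
        c2 = self.layer1(self.stem(x))
        c3 = self.layer2(c2)
        c4 = self.layer3(c3)
        c5 = self.layer4(c4)
        return PyramidFeatures(
            (FeatureMap(c3, 8), FeatureMap(c4, 16), FeatureMap(c5, 32))
        )
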