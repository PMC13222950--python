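"""Detector assembly: baseline RT-DETR-R18 and the DSA-DET variants.

``build_detector`` wires a backbone (ResNet-18 or DASPMNet), the hybrid
encoder (softmax AIFI or linear-attention HSATE on the top level; plain
or ESCU upsampling in the fusion path) and the deformable-attention
decoder, according to an ablation-style variant flag.  The profiler
reports trainable parameters and forward FLOPs (2 × multiply–accumulates
of the dense operations) at a declared input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import DASPMNet, DASPMNetConfig
from .decoder import RTDETRDecoder
from .neck import HybridEncoder
from .nn.tensor import Tensor, counting_macs, no_grad
from .resnet import ResNet18

__all__ = [
    "VARIANTS",
    "DetectorConfig",
    "Detection",
    "ProfileReport",
    "Detector",
    "build_detector",
    "forward_detect",
    "count_params",
    "count_flops",
]

# variant -> (use_daspmnet, use_hsate, use_escu); mirrors the ablation grid
VARIANTS = {
    "baseline": (False, False, False),
    "daspmnet_only": (True, False, False),
    "hsate_only": (False, True, False),
    "escu_only": (False, False, True),
    "daspmnet_hsate": (True, True, False),
    "daspmnet_escu": (True, False, True),
    "hsate_escu": (False, True, True),
    "dsadet": (True, True, True),
}


@dataclass
class DetectorConfig:
    variant: str = "dsadet"
    num_classes: int = 5
    num_queries: int = 300
    input_size: int = 640
    hidden_dim: int = 256
    num_heads: int = 8
    ffn_dim: int = 1024
    num_decoder_layers: int = 3
    num_points: int = 4
    csp_hidden: int = 128
    csp_blocks: int = 3
    backbone_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    daspmnet: dict = field(default_factory=dict)
    alpha_init: float = 1.0
    maem_dropout: float = 0.1
    escu_groups: int = 4
    escu_shift: int = 1
    score_threshold: float = 0.25

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )
        if isinstance(self.backbone_widths, list):
            self.backbone_widths = tuple(self.backbone_widths)


@dataclass
class Detection:
    """One detected object: class id, confidence and an xyxy pixel box
    (0-based, half-open)."""

    class_id: int
    score: float
    box: tuple[float, float, float, float]


@dataclass
class ProfileReport:
    params_millions: float
    gflops: float
    input_size: int
    counting_convention: str = (
        "FLOPs = 2 x MACs of conv/matmul/sampling ops; normalization and "
        "elementwise ops not counted"
    )


class Detector(nn.Module):
    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        self.cfg = cfg
        use_daspm, use_hsate, use_escu = VARIANTS[cfg.variant]
        if use_daspm:
            bcfg = DASPMNetConfig.from_dict(cfg.daspmnet) if cfg.daspmnet else (
                DASPMNetConfig(stage_widths=cfg.backbone_widths)
            )
            self.backbone = DASPMNet(bcfg)
        else:
            self.backbone = ResNet18(cfg.backbone_widths)
        self.encoder = HybridEncoder(
            self.backbone.out_channels,
            hidden_dim=cfg.hidden_dim,
            use_hsate=use_hsate,
            use_escu=use_escu,
            num_heads=cfg.num_heads,
            ffn_dim=cfg.ffn_dim,
            csp_hidden=cfg.csp_hidden,
            csp_blocks=cfg.csp_blocks,
            alpha_init=cfg.alpha_init,
            maem_dropout=cfg.maem_dropout,
            escu_groups=cfg.escu_groups,
            escu_shift=cfg.escu_shift,
        )
        self.decoder = RTDETRDecoder(
            num_classes=cfg.num_classes,
            embed_dim=cfg.hidden_dim,
            num_queries=cfg.num_queries,
            num_layers=cfg.num_decoder_layers,
            num_heads=cfg.num_heads,
            ffn_dim=cfg.ffn_dim,
            num_points=cfg.num_points,
        )

    def forward(self, images: Tensor) -> dict:
        """``images``: (B, 3, H, W) in [0, 1]."""
        pyramid = self.backbone(images)
        levels = self.encoder(pyramid)
        return self.decoder(levels)


def build_detector(cfg: DetectorConfig) -> Detector:
    return Detector(cfg)


def forward_detect(
    detector: Detector,
    image: np.ndarray,
    score_threshold: float | None = None,
) -> list[Detection]:
    """Run one RGB image (H, W, 3, uint8 or float in [0,1]) through the
    detector in eval mode; returns score-filtered detections (no NMS)."""
    cfg = detector.cfg
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    H, W = image.shape[:2]
    if H != cfg.input_size or W != cfg.input_size:
        raise ValueError(
            f"expected {cfg.input_size}x{cfg.input_size} input, got {H}x{W}"
        )
    x = image.astype(np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    x = x.transpose(2, 0, 1)[None]
    detector.eval()
    with no_grad():
        out = detector(Tensor(x))
    logits = out["logits"][-1].data[0]  # (k, K+1)
    boxes = out["boxes"][-1].data[0]  # (k, 4) normalized cxcywh
    probs = np.exp(logits - logits.max(axis=-1, keepdims=True))
    probs /= probs.sum(axis=-1, keepdims=True)
    fg = probs[:, : cfg.num_classes]
    class_ids = fg.argmax(axis=-1)
    scores = fg.max(axis=-1)
    cx, cy, w, h = boxes.T
    xyxy = np.stack(
        [(cx - w / 2) * W, (cy - h / 2) * H, (cx + w / 2) * W, (cy + h / 2) * H],
        axis=-1,
    )
    xyxy = np.clip(xyxy, 0, [W, H, W, H])
    thresh = cfg.score_threshold if score_threshold is None else score_threshold
    dets = [
        Detection(int(c), float(s), tuple(float(v) for v in b))
        for c, s, b in zip(class_ids, scores, xyxy)
        if s >= thresh and b[2] > b[0] and b[3] > b[1]
    ]
    dets.sort(key=lambda d: -d.score)
    return dets


def count_params(detector: nn.Module, input_size: int | None = None) -> ProfileReport:
    size = input_size or getattr(getattr(detector, "cfg", None), "input_size", 0)
    return ProfileReport(
        params_millions=detector.num_parameters() / 1e6,
        gflops=0.0,
        input_size=size,
    )


def count_flops(detector: Detector, input_size: int | None = None) -> ProfileReport:
    size = input_size or detector.cfg.input_size
    x = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    detector.eval()
    with no_grad(), counting_macs() as macs:
        detector(x)
    return ProfileReport(
        params_millions=detector.num_parameters() / 1e6,
        gflops=2.0 * macs[0] / 1e9,
        input_size=size,
    )
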