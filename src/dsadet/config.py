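"""Run configuration: presets, YAML loading and precedence.

Training defaults follow the published recipe: 640 input, batch 4,
AdamW at lr 1e-4 / weight decay 1e-4, 300 max epochs, 2000 warm-up
iterations.  Two detector presets exist: ``full`` (the profiled
architecture) and ``desk`` (a small-width, small-input configuration
sized for CPU experiments and the overfit sanity checks).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .detector import DetectorConfig

__all__ = ["TrainConfig", "detector_preset", "load_yaml_config", "resolve_config"]


@dataclass
class TrainConfig:
    input_size: int = 640
    batch_size: int = 4
    max_epochs: int = 300
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    momentum: float = 0.9
    warmup_iters: int = 2000
    optimizer: str = "adamw"


_DESK = dict(
    num_queries=30,
    input_size=64,
    hidden_dim=64,
    num_heads=4,
    ffn_dim=128,
    num_decoder_layers=2,
    csp_hidden=32,
    csp_blocks=1,
    backbone_widths=(16, 32, 64, 128),
    daspmnet=dict(
        stem_channels=16,
        stage_widths=(16, 32, 64, 128),
        num_sab=(1, 1, 1, 1),
        prompt_dim=8,
        value_groups=(1, 1, 1, 1),
    ),
)


def detector_preset(name: str, variant: str = "dsadet", **overrides) -> DetectorConfig:
    """``full`` or ``desk`` detector preset, with keyword overrides."""
    if name == "full":
        base: dict = {}
    elif name == "desk":
        base = dict(_DESK)
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return DetectorConfig(variant=variant, **base)


def load_yaml_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def resolve_config(
    file_cfg: dict | None = None, cli_overrides: dict | None = None
) -> dict:
    """Merge with precedence: CLI flags > config file > defaults."""
    out = {
        "preset": "full",
        "variant": "dsadet",
        "train": asdict(TrainConfig()),
        "detector": {},
    }
    for layer in (file_cfg or {}), (cli_overrides or {}):
        for k, v in layer.items():
            if k in ("train", "detector") and isinstance(v, dict):
                out[k].update({kk: vv for kk, vv in v.items() if vv is not None})
            elif v is not None:
                out[k] = v
    return out
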