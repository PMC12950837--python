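"""Run configuration: every knob of the detector, YAML round-trippable.

The default values reproduce the reference 256x256 configuration (ResNet18-style
pyramid, widths 64/128/256/512, eight coupling blocks per scale, Adam at 2e-4).
`RunConfig.tiny_test()` is the desk-scale profile used throughout the test
suite: 64x64 phantoms, a small randomly initialized backbone and a short
optimization schedule that still separates lesions from background texture.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

SUPPORTED_RESOLUTIONS = (64, 128, 256, 512)


class ConfigurationError(ValueError):
    """Invalid or inconsistent configuration."""


@dataclass
class BackboneConfig:
    name: str = "table2-resnet18"
    channel_widths: Tuple[int, int, int, int] = (64, 128, 256, 512)
    weights_path: Optional[str] = None
    #: insert the extra stride so level 1 sits at H/8 (the printed scheme);
    #: False falls back to the standard ResNet strides (level 1 at H/4)
    extra_stem_downsample: bool = True
    freeze: bool = True


@dataclass
class EdgeConfig:
    egm_enabled: bool = True
    eam_enabled: bool = True
    cab_reduction: int = 16
    #: how the edge feature is merged into F4 when EGM is on: eam | add | mul
    aggregation: str = "eam"


@dataclass
class FlowConfig:
    depth: int = 8
    clamp: float = 1.9
    condition_dim: int = 128
    hidden_ratio: float = 1.0


@dataclass
class FusionConfig:
    enabled: bool = True
    kernel_size: int = 1
    bottleneck_ratio: int = 4
    #: post_fusion computes the likelihood loss on the fused maps, pre_fusion on
    #: the raw decoder outputs
    loss_on: str = "post_fusion"
    upsample: str = "nearest"


@dataclass
class ScoringConfig:
    top_n: int = 100
    pixel_upsample: str = "bilinear"


@dataclass
class OptimizerConfig:
    lr: float = 2e-4
    epochs: int = 100
    batch_size: int = 32


@dataclass
class RunConfig:
    resolution: int = 256
    seed: int = 0
    data_root: Optional[str] = None
    output_dir: str = "runs"
    device: str = "cpu"
    normalize_mean: float = 0.5
    normalize_std: float = 0.5
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    edge: EdgeConfig = field(default_factory=EdgeConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self):
        self.validate()

    # ---- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.resolution not in SUPPORTED_RESOLUTIONS:
            raise ConfigurationError(
                f"resolution {self.resolution} not in supported set {SUPPORTED_RESOLUTIONS}"
            )
        if self.resolution % 64:
            raise ConfigurationError("image side must be divisible by 64")
        if self.backbone.name not in ("table2-resnet18", "tiny-test-backbone"):
            raise ConfigurationError(f"unknown backbone {self.backbone.name!r}")
        if len(self.backbone.channel_widths) != 4:
            raise ConfigurationError("channel_widths must have four levels")
        if self.flow.condition_dim % 4:
            raise ConfigurationError("flow.condition_dim must be divisible by 4")
        if self.flow.depth < 1:
            raise ConfigurationError("flow.depth must be positive")
        if self.edge.aggregation not in ("eam", "add", "mul"):
            raise ConfigurationError(f"unknown aggregation {self.edge.aggregation!r}")
        if self.fusion.loss_on not in ("post_fusion", "pre_fusion"):
            raise ConfigurationError(f"unknown loss_on {self.fusion.loss_on!r}")

    # ---- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["backbone"]["channel_widths"] = list(self.backbone.channel_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("backbone", BackboneConfig),
            ("edge", EdgeConfig),
            ("flow", FlowConfig),
            ("fusion", FusionConfig),
            ("scoring", ScoringConfig),
            ("optimizer", OptimizerConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        cfg = cls(**d)
        cfg.backbone.channel_widths = tuple(cfg.backbone.channel_widths)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    # ---- profiles -------------------------------------------------------
    @classmethod
    def tiny_test(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Desk-scale profile: 64x64 input, small random backbone, short schedule."""
        cfg = cls(
            resolution=64,
            seed=seed,
            backbone=BackboneConfig(name="tiny-test-backbone", channel_widths=(4, 8, 16, 32)),
            edge=EdgeConfig(cab_reduction=4),
            flow=FlowConfig(depth=8, condition_dim=16),
            scoring=ScoringConfig(top_n=8),
            optimizer=OptimizerConfig(lr=1e-3, epochs=5, batch_size=8),
        )
        for key, val in overrides.items():
            setattr(cfg, key, val)
        cfg.validate()
        return cfg
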