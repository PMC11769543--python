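"""Experiment configuration: one flat, fully self-describing YAML file.

Every tunable of the workflow lives in one schema-validated document with
documented defaults (expansion 0.25, target spacing 1.0 mm, percentile
0.5, IoU threshold 0.25, size bins 4/7 cm ...).  Unknown keys fail hard —
a typo never silently falls back to a default — and the fully resolved
config round-trips losslessly through serialization, so the file written
next to an experiment's outputs reproduces it exactly.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PreprocessBlock(_Block):
    target_spacing: float = 1.0
    percentile: float = 0.5
    pooled: bool = True

    @field_validator("target_spacing")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("target_spacing must be positive")
        return v


class AugmentBlock(_Block):
    rotation_range_deg: float = 30.0
    rotation_prob: float = 0.3
    scale_range: Tuple[float, float] = (0.85, 1.25)
    scale_prob: float = 0.3
    mirror_axes: Tuple[int, ...] = (0, 1, 2)
    mirror_prob: float = 0.5
    transpose_enabled: bool = True
    transpose_prob: float = 0.2
    gamma_range: Tuple[float, float] = (0.7, 1.5)
    gamma_prob: float = 0.3


class OrganNetBlock(_Block):
    encoder_steps: int = 4
    transformer_blocks_per_step: int = 2
    window_input_size: int = 128
    base_channels: int = 24
    window_size: int = 7
    num_heads: int = 3
    backend: str = "swin"


class TumorNetBlock(_Block):
    n_stages: int = 6
    channels: Tuple[int, ...] = (32, 64, 128, 256, 320, 320)
    residual_blocks: Tuple[int, ...] = (1, 3, 4, 6, 6, 6)
    decoder_convs_per_stage: int = 1
    attention_gates: bool = True
    patch_size: Tuple[int, int, int] = (192, 128, 128)
    batch_size: int = 5
    leaky_slope: float = 0.01


class TrainBlock(_Block):
    optimizer: str = "sgd"
    lr: float = 1e-3
    momentum: float = 0.99
    nesterov: bool = True
    weight_decay: float = 0.0
    epochs: int = 20
    patches_per_volume: int = 2
    batch_size: int = 2
    patch_size: Tuple[int, int, int] = (32, 32, 32)
    foreground_oversampling: float = 0.5


class PipelineBlock(_Block):
    expansion: float = 0.25
    organ_threshold: float = 0.5
    tumor_threshold: float = 0.5
    organ_window: Tuple[int, int, int] = (64, 64, 64)
    tumor_window: Tuple[int, int, int] = (32, 32, 32)
    overlap: float = 0.5


class MetricsBlock(_Block):
    iou_threshold: float = 0.25
    small_max_cm: float = 4.0
    medium_max_cm: float = 7.0
    diameter_mode: str = "axial"
    min_component_voxels: int = 8


class PathsBlock(_Block):
    data_dir: str = "data"
    output_dir: str = "output"
    checkpoint_dir: str = "checkpoints"


class ExperimentConfig(_Block):
    paths: PathsBlock = PathsBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    augment: AugmentBlock = AugmentBlock()
    organ_net: OrganNetBlock = OrganNetBlock()
    tumor_net: TumorNetBlock = TumorNetBlock()
    train_organ: TrainBlock = TrainBlock(optimizer="adamw", lr=3.5e-4, weight_decay=1e-2)
    train_tumor: TrainBlock = TrainBlock()
    pipeline: PipelineBlock = PipelineBlock()
    metrics: MetricsBlock = MetricsBlock()
    seed: int = 0

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        canon = json.dumps(self.resolved_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved_dict(), fh, sort_keys=True)


def desk_preset(seed: int = 0) -> ExperimentConfig:
    """A CPU-scale preset: 3-stage tumor net, 32-cubed patches, batch 2,
    CNN organ backend, sized for 64-cubed phantom volumes."""
    cfg = ExperimentConfig(seed=seed)
    cfg.tumor_net = TumorNetBlock(
        n_stages=3, channels=(8, 16, 32), residual_blocks=(1, 2, 2),
        patch_size=(32, 32, 32), batch_size=2,
    )
    cfg.organ_net = OrganNetBlock(backend="cnn", window_input_size=64,
                                  base_channels=8, window_size=4, num_heads=2)
    cfg.pipeline = PipelineBlock(organ_window=(48, 48, 48), tumor_window=(32, 32, 32))
    cfg.train_organ = TrainBlock(optimizer="adamw", lr=3e-3, weight_decay=1e-4,
                                 epochs=30, patch_size=(48, 48, 48),
                                 foreground_oversampling=0.0)
    cfg.train_tumor = TrainBlock(optimizer="adamw", lr=3e-3, weight_decay=1e-4,
                                 epochs=25, patch_size=(32, 32, 32),
                                 foreground_oversampling=0.6)
    return cfg


def make_tumor_net_config(cfg: ExperimentConfig):
    from .tumor_net import TumorNetConfig

    b = cfg.tumor_net
    return TumorNetConfig(
        n_stages=b.n_stages, channels=tuple(b.channels),
        residual_blocks=tuple(b.residual_blocks),
        decoder_convs_per_stage=b.decoder_convs_per_stage,
        attention_gates=b.attention_gates, patch_size=tuple(b.patch_size),
        batch_size=b.batch_size, leaky_slope=b.leaky_slope, seed=cfg.seed,
    )


def make_organ_net_config(cfg: ExperimentConfig):
    from .stage1 import OrganNetConfig

    b = cfg.organ_net
    return OrganNetConfig(
        encoder_steps=b.encoder_steps,
        transformer_blocks_per_step=b.transformer_blocks_per_step,
        window_input_size=b.window_input_size, base_channels=b.base_channels,
        window_size=b.window_size, num_heads=b.num_heads, backend=b.backend,
        seed=cfg.seed,
    )


def make_train_config(cfg: ExperimentConfig, stage: str):
    from .augment import AugmentParams
    from .training import TrainConfig

    b = cfg.train_organ if stage == "organ" else cfg.train_tumor
    aug = AugmentParams(**cfg.augment.model_dump())
    return TrainConfig(
        stage=stage, optimizer=b.optimizer, lr=b.lr, momentum=b.momentum,
        nesterov=b.nesterov, weight_decay=b.weight_decay, epochs=b.epochs,
        patches_per_volume=b.patches_per_volume, batch_size=b.batch_size,
        patch_size=tuple(b.patch_size),
        foreground_oversampling=b.foreground_oversampling,
        target_label="kidney" if stage == "organ" else "tumor",
        augment=aug, seed=cfg.seed,
    )


def make_pipeline_config(cfg: ExperimentConfig):
    from .pipeline import PipelineConfig

    b = cfg.pipeline
    return PipelineConfig(
        target_spacing=cfg.preprocess.target_spacing, expansion=b.expansion,
        organ_threshold=b.organ_threshold, tumor_threshold=b.tumor_threshold,
        organ_window=tuple(b.organ_window), tumor_window=tuple(b.tumor_window),
        overlap=b.overlap,
    )


def load_config(path: Optional[str] = None) -> ExperimentConfig:
    """Load a YAML experiment config, filling documented defaults.

    An empty (or absent) file yields the full default configuration;
    unknown keys raise with the offending key named.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return ExperimentConfig(**raw)
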