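"""YAML run configuration, validated with pydantic, plus seed fan-out.

One global seed drives every stage through a named substream
(:func:`stage_seed`), so a whole pipeline rerun with the same config file
is deterministic end to end.
"""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml
from pydantic import BaseModel, Field

from .features import EncoderSpec
from .model import CamilConfig, FUSION_MODES
from .preprocess import TilingConfig
from .synth_data import SynthConfig
from .train_eval import TrainConfig


class TilingSection(BaseModel):
    patch_size: int = 256
    magnifications: Tuple[str, ...] = ("20x",)
    min_tissue_fraction: float = Field(0.35, ge=0.0, le=1.0)
    stride: Optional[int] = None

    def build(self) -> TilingConfig:
        return TilingConfig(**self.model_dump())


class EncoderSection(BaseModel):
    name: str = "toy_histogram"
    output_dim: int = Field(512, ge=1)
    normalize: bool = False

    def build(self) -> EncoderSpec:
        return EncoderSpec(**self.model_dump())


class ModelSection(BaseModel):
    in_dim: int = Field(512, ge=1)
    model_dim: int = Field(256, ge=1)
    pool_hidden: int = Field(128, ge=1)
    fusion_mode: str = "spatial_then_channel"

    def build(self, seed: int) -> CamilConfig:
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        return CamilConfig(seed=seed, **self.model_dump())


class TrainSection(BaseModel):
    learning_rate: float = Field(1e-4, gt=0)
    weight_decay: float = Field(1e-5, ge=0)
    epochs: int = Field(50, ge=1)
    early_stop_patience: int = Field(10, ge=1)
    threshold: float = Field(0.5, gt=0, lt=1)
    folds: int = Field(10, ge=2)
    val_fraction: float = Field(0.2, gt=0, lt=1)

    def build(self, seed: int) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


class SynthSection(BaseModel):
    n_bags: int = Field(200, ge=2)
    n_min: int = Field(20, ge=1)
    n_max: int = Field(60, ge=1)
    feature_dim: int = Field(512, ge=1)
    witness_rate: float = Field(0.1, gt=0, le=1)
    effect_size: float = Field(2.0, ge=0)
    signal_channels: int = Field(8, ge=1)
    positive_bag_fraction: float = Field(0.5, gt=0, lt=1)

    def build(self, seed: int) -> SynthConfig:
        return SynthConfig(seed=seed, **self.model_dump())


class PathsSection(BaseModel):
    workdir: str = "camil_run"
    store: str = "features.h5"
    checkpoint: str = "model.npz"

    def resolve(self, name: str) -> Path:
        p = Path(getattr(self, name))
        return p if p.is_absolute() else Path(self.workdir) / p


class RunConfig(BaseModel):
    seed: int = 0
    log_level: str = "INFO"
    paths: PathsSection = PathsSection()
    tiling: TilingSection = TilingSection()
    encoder: EncoderSection = EncoderSection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    synth: SynthSection = SynthSection()


def load_config(path: Union[str, Path]) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(payload)


def dump_config(cfg: RunConfig, path: Optional[Union[str, Path]] = None) -> str:
    text = yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the semantic config content."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the global seed (< 2^31)."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
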