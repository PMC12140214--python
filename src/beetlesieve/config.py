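"""Validated YAML pipeline configuration.

Every pipeline constant (0.2 test fraction, k = 5, batch 64 / 5 epochs /
learning rate 0.003, augmentation probability 0.8, 224 px inputs, decision
boundary t = 0.8) appears here as a named, overridable default. Unknown
keys are rejected at load time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .training import AugmentConfig, TrainConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationSection(_Strict):
    margin: int = 0
    min_objects: int = 1

    @field_validator("margin")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("margin must be >= 0")
        return v


class SplitsSection(_Strict):
    test_frac: float = 0.2
    k: int = 5
    seed: int = 0

    @field_validator("test_frac")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("test_frac must lie in (0, 1)")
        return v


class TrainingSection(_Strict):
    batch_size: int = 64
    epochs: int = 5
    learning_rate: float = 0.003
    warmup_epochs: int = 1
    label_smoothing_eps: float = 0.1
    augment_prob: float = 0.8
    image_size: int = 224
    seed: int = 0
    backbone_name: str = "tiny_cnn"
    early_stop_patience: Optional[int] = None

    def to_train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            warmup_epochs=self.warmup_epochs,
            label_smoothing_eps=self.label_smoothing_eps,
            augment_prob=self.augment_prob,
            image_size=self.image_size,
            seed=self.seed,
            backbone_name=self.backbone_name,
            augment=AugmentConfig(prob=self.augment_prob),
            early_stop_patience=self.early_stop_patience,
        )


class OpensetSection(_Strict):
    t: float = 0.8
    method: str = "formula"
    t_open: Optional[float] = None

    @field_validator("t", "t_open")
    @classmethod
    def _t_range(cls, v):
        if v is not None and not (0.0 < v < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")
        return v

    @field_validator("method")
    @classmethod
    def _method(cls, v: str) -> str:
        if v not in ("formula", "max_prob"):
            raise ValueError("method must be 'formula' or 'max_prob'")
        return v


class EvaluationSection(_Strict):
    grid_size: int = 101


class PipelineConfig(_Strict):
    segmentation: SegmentationSection = SegmentationSection()
    splits: SplitsSection = SplitsSection()
    training: TrainingSection = TrainingSection()
    openset: OpensetSection = OpensetSection()
    evaluation: EvaluationSection = EvaluationSection()

    @classmethod
    def load(cls, path: str | Path | None) -> "PipelineConfig":
        if path is None:
            return cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
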