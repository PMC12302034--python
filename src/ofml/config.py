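"""Serializable training configuration.

Defaults follow the published training recipe: Adam with learning rate
0.01, first-moment decay ("momentum") 0.8, weight decay 5e-4, distillation
temperature T = 4, batch size 64, 300 epochs, a 70:30 train/test split,
224 px inputs and four-fold Mixup expansion.  Every gap-filling default
(view widths, depths, head counts, loss weights) is also carried here so a
round-tripped YAML file reproduces a run exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

VARIANTS = ("A", "B", "C", "D", "E", "F", "G", "full", "AFC1", "AFC2", "AFC3")


class MixupSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    alpha: float = Field(0.2, gt=0)
    factor: int = Field(4, ge=1)
    within_class: bool = False


class CNNSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    block_counts: tuple[int, ...] = (3, 4, 6, 3)
    base_width: int = Field(64, ge=1)
    small_stem: bool = False
    tap_stage: int | Literal["auto"] = "auto"


class MVTSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    patch_size: int = Field(16, ge=1)
    view_dims: tuple[int, ...] = (256, 384, 512)
    layers_per_view: int = Field(4, ge=1)
    global_dim: int = Field(512, ge=1)
    global_depth: int = Field(4, ge=1)
    heads: int = Field(8, ge=1)
    tap_layer: int = Field(3, ge=1)


class LossSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    w_epkt: float = Field(1.0, ge=0)
    w_fusion_ce: float = Field(1.0, ge=0)
    literal_total: bool = False  # drop the two auxiliary terms entirely


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: float = Field(0.01, gt=0)
    adam_beta1: float = Field(0.8, gt=0, lt=1)
    adam_beta2: float = Field(0.999, gt=0, lt=1)
    weight_decay: float = Field(5e-4, ge=0)
    temperature: float = Field(4.0, gt=0)
    batch_size: int = Field(64, ge=1)
    epochs: int = Field(300, ge=0)
    train_frac: float = Field(0.7, gt=0, lt=1)
    image_size: int = Field(224, ge=32)
    seed: int = 0
    variant: Literal[*VARIANTS] = "full"
    checkpoint_every: int = Field(0, ge=0)  # 0 = only final
    eval_every: int = Field(0, ge=0)  # 0 = never during training
    mixup: MixupSettings = MixupSettings()
    cnn: CNNSettings = CNNSettings()
    mvt: MVTSettings = MVTSettings()
    loss: LossSettings = LossSettings()

    @property
    def effective_loss_weights(self) -> tuple[float, float]:
        if self.loss.literal_total:
            return 0.0, 0.0
        return self.loss.w_epkt, self.loss.w_fusion_ce

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "TrainConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            source = Path(source).read_text()
        return cls.model_validate(yaml.safe_load(source))


def tiny_config(seed: int = 0) -> TrainConfig:
    """Desk-scale configuration: 32 px inputs, reduced widths and depths.

    Used by the self-contained end-to-end study; Adam runs at 1e-3 here,
    the conventional setting for small transformer stacks.
    """
    return TrainConfig(
        learning_rate=1e-3,
        epochs=30,
        batch_size=16,
        image_size=32,
        seed=seed,
        cnn=CNNSettings(block_counts=(1, 1, 1, 1), base_width=8, small_stem=True),
        mvt=MVTSettings(
            patch_size=8,
            view_dims=(16, 24, 32),
            layers_per_view=1,
            global_dim=32,
            global_depth=3,
            heads=2,
            tap_layer=3,
        ),
    )
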