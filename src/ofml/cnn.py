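"""ResNet-style local-feature branch.

A bottleneck residual network (ResNet-50 layout by default) that, besides
its class logits, exposes a tapped intermediate feature map for the fusion
classifier.  Residual stages are numbered 1..4 (the stem is stage 0); at
224 px input the standard widths give stage outputs (256,56,56),
(512,28,28), (1024,14,14), (2048,7,7).  The default tap is resolved *by
shape* — whichever stage carries 512 channels, i.e. (512, 28, 28) at
224 px — because the printed shape is the only unambiguous anchor for
which "convolutional layer" feeds the fusion classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .autodiff import nn
from .exceptions import ConfigurationError, DataError


@dataclass
class BranchOutput:
    """Logits plus the tapped intermediate feature map of one backbone."""

    logits: Tensor  # (B, M)
    feature_map: Tensor  # (B, C, H, W)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, rng, stride: int = 1):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, rng, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class ResNetBranch(nn.Module):
    """Bottleneck CNN with an intermediate tap.

    Parameters
    ----------
    block_counts
        Bottlenecks per residual stage; (3, 4, 6, 3) is ResNet-50.
    base_width
        Mid-width of stage 1 (64 for the standard network).  Stage output
        channels are ``4 * base_width * 2**(stage-1)``.
    tap_stage
        1-4, or ``"auto"`` to pick the stage whose output carries
        ``4 * base_width * 2`` channels (512 for the standard width — the
        printed fusion-input shape).
    small_stem
        Replace the 7x7/2 stem + max-pool by a 3x3/1 convolution, keeping
        full resolution for small (e.g. 32 px) inputs.
    """

    def __init__(
        self,
        num_classes: int,
        rng: np.random.Generator,
        block_counts: tuple[int, ...] = (3, 4, 6, 3),
        base_width: int = 64,
        tap_stage: int | str = "auto",
        small_stem: bool = False,
    ):
        super().__init__()
        stem_ch = base_width
        if small_stem:
            self.stem = nn.Sequential(
                nn.Conv2d(3, stem_ch, 3, rng, stride=1, padding=1, bias=False),
                nn.BatchNorm2d(stem_ch),
                nn.ReLU(),
            )
        else:
            self.stem = nn.Sequential(
                nn.Conv2d(3, stem_ch, 7, rng, stride=2, padding=3, bias=False),
                nn.BatchNorm2d(stem_ch),
                nn.ReLU(),
                nn.MaxPool2d(3, 2, 1),
            )
        self.stages = nn.ModuleList()
        in_ch = stem_ch
        self.stage_channels: list[int] = []
        for s, n_blocks in enumerate(block_counts):
            mid = base_width * 2**s
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and s > 0) else 1
                blocks.append(Bottleneck(in_ch, mid, rng, stride=stride))
                in_ch = mid * Bottleneck.expansion
            self.stages.append(nn.Sequential(*blocks))
            self.stage_channels.append(in_ch)
        self.head = nn.Linear(in_ch, num_classes, rng)

        if tap_stage == "auto":
            target = 4 * base_width * 2  # 512-channel stage at standard width
            tap_stage = 1 + self.stage_channels.index(target)
        if not 1 <= int(tap_stage) <= len(self.stages):
            raise ConfigurationError(f"tap_stage must be in 1..{len(self.stages)}")
        self.tap_stage = int(tap_stage)

    @property
    def tap_channels(self) -> int:
        return self.stage_channels[self.tap_stage - 1]

    def forward(self, x: Tensor) -> BranchOutput:
        if x.ndim != 4 or x.shape[1] != 3:
            raise DataError(f"expected (B, 3, H, W) input, got {x.shape}")
        out = self.stem(x)
        tapped = None
        for s, stage in enumerate(self.stages, start=1):
            out = stage(out)
            if s == self.tap_stage:
                tapped = out
        pooled = out.mean(axis=(2, 3))
        logits = self.head(pooled)
        return BranchOutput(logits=logits, feature_map=tapped)


def cnn_forward(model: ResNetBranch, batch: Tensor | np.ndarray) -> BranchOutput:
    """Run the CNN branch on a (B, 3, H, W) batch."""
    if not isinstance(batch, Tensor):
        batch = Tensor(batch)
    return model(batch)
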