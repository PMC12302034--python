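"""Ensemble and adaptive-fusion classification heads.

The ensemble classifier is the element-wise arithmetic mean of the two
branch logit vectors.  The adaptive fusion classifier pools each branch's
tapped feature map to 1x1 by adaptive average pooling, concatenates the
channel vectors (c1 + c2 channels; 1024 for the standard 512 + 512 taps)
and applies a pointwise (1x1) convolution with bias down to the number of
classes C — so its parameter count is exactly (c1 + c2) * C + C, with no
further tunable block, and it accepts taps of arbitrary spatial size.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, functional as F, nn
from .exceptions import DataError


def ensemble_logits(a1: Tensor, a2: Tensor) -> Tensor:
    """Element-wise mean of the two branch logit vectors."""
    if a1.shape != a2.shape:
        raise DataError(f"logit shape mismatch: {a1.shape} vs {a2.shape}")
    return (a1 + a2) * 0.5


class FusionHead(nn.Module):
    def __init__(self, channels1: int, channels2: int, num_classes: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = channels1 + channels2
        self.num_classes = num_classes
        self.pointwise = nn.Conv2d(self.in_channels, num_classes, 1, rng, bias=True)

    def forward(self, fm1: Tensor, fm2: Tensor) -> Tensor:
        pooled1 = F.global_avg_pool2d(fm1)  # (B, c1)
        pooled2 = F.global_avg_pool2d(fm2)  # (B, c2)
        merged = concat([pooled1, pooled2], axis=1)
        b, c = merged.shape
        if c != self.in_channels:
            raise DataError(f"fusion head expects {self.in_channels} channels, got {c}")
        logits = self.pointwise(merged.reshape(b, c, 1, 1))
        return logits.reshape(b, self.num_classes)


def fusion_forward(head: FusionHead, fm1: Tensor, fm2: Tensor) -> Tensor:
    """Pool, concatenate and project two feature maps to class logits."""
    return head(fm1, fm2)
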