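"""Mixup training-set expansion.

Mixup draws a mixing weight lam ~ Beta(alpha, alpha) and forms convex
combinations of image pairs and of their label distributions, so the
expanded set carries soft labels on the class simplex.  Expansion by an
integer ``factor`` keeps the originals as the first copy (retaining the
unmodified samples) and appends ``factor - 1`` mixed copies; the test split
is never expanded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledImageSet
from .exceptions import ConfigurationError, DataError


@dataclass
class MixupConfig:
    alpha: float = 0.2
    factor: int = 4
    seed: int = 0
    include_originals: bool = True
    within_class: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise ConfigurationError("mixup alpha must be positive")
        if self.factor < 1:
            raise ConfigurationError("mixup factor must be >= 1")


def mixup_pair(
    x_i: np.ndarray,
    y_i: np.ndarray,
    x_j: np.ndarray,
    y_j: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Convex combination of two images and their label distributions."""
    if x_i.shape != x_j.shape:
        raise DataError(f"image shape mismatch: {x_i.shape} vs {x_j.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ConfigurationError(f"lam must lie in [0, 1], got {lam}")
    y_i = np.asarray(y_i, dtype=np.float64)
    y_j = np.asarray(y_j, dtype=np.float64)
    x = lam * x_i + (1.0 - lam) * x_j
    y = lam * y_i + (1.0 - lam) * y_j
    return x.astype(x_i.dtype), y


def expand_dataset(data: LabeledImageSet, cfg: MixupConfig) -> LabeledImageSet:
    """Expand ``data`` to exactly ``cfg.factor`` times its size.

    The first copy is the untouched originals (when ``include_originals``);
    each remaining copy pairs every sample with a partner drawn uniformly —
    from the whole set by default, within the same class when
    ``cfg.within_class`` — and mixes with lam ~ Beta(alpha, alpha).
    """
    if len(data) == 0:
        raise DataError("cannot expand an empty dataset")
    rng = np.random.default_rng(cfg.seed)
    base_labels = data.label_simplex()
    n = len(data)

    images: list[np.ndarray] = []
    soft: list[np.ndarray] = []
    hard: list[int] = []

    n_mixed_copies = cfg.factor - 1 if cfg.include_originals else cfg.factor
    if cfg.include_originals:
        images.extend(data.images)
        soft.extend(base_labels)
        hard.extend(data.labels)

    for _ in range(n_mixed_copies):
        for i in range(n):
            if cfg.within_class:
                pool = np.flatnonzero(data.labels == data.labels[i])
                j = int(rng.choice(pool))
            else:
                j = int(rng.integers(n))
            lam = float(rng.beta(cfg.alpha, cfg.alpha))
            x, y = mixup_pair(data.images[i], base_labels[i], data.images[j], base_labels[j], lam)
            images.append(x)
            soft.append(y)
            hard.append(int(np.argmax(y)))

    return LabeledImageSet(
        images=images,
        labels=np.asarray(hard),
        class_names=list(data.class_names),
        source=data.source,
        soft_labels=np.asarray(soft, dtype=np.float32),
    )
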