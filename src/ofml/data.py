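"""Datasets: synthetic histology-like image generation and folder readers.

The synthetic generator emulates the visual statistics that make
hematoxylin & eosin (H&E) stained tissue classifiable: a pink
(eosin-stained cytoplasm) background scattered with darker blue-purple
elliptical "nuclei".  Classes differ in nucleus density, nucleus size and
stain darkness, which is what separates e.g. benign from malignant tissue
at a coarse level (malignant fields are more nucleus-dense with more
pleomorphic, hyperchromatic nuclei).  The classes are deliberately
separable even by a pixel-mean centroid rule, so that every downstream
stage of the framework can be exercised end-to-end without downloading a
real benchmark.

Folder readers cover a flat ``root/<class>/<image>`` layout and the two
public breast-histopathology benchmark layouts (binary/8-subtype trees
with magnification subdirectories, and a four-class flat tree).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}

#: canonical class directories of the four-class microscopy layout
BACH_CLASSES = ("Benign", "InSitu", "Invasive", "Normal")


@dataclass
class LabeledImageSet:
    """Images with integer class labels.

    ``images`` are float arrays of shape (H, W, 3) with values in [0, 1];
    ``labels[i]`` indexes into ``class_names``.  ``soft_labels`` (rows on the
    class simplex) are populated by Mixup expansion; for un-augmented sets it
    is ``None`` and the hard labels are authoritative.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    source: str = "synthetic"
    soft_labels: np.ndarray | None = None
    magnifications: list[str] | None = None
    nucleus_masks: list[np.ndarray] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise DataError("images and labels disagree in length")
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise DataError("label index outside class_names")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise DataError(f"images must share one shape, got {shapes}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_shape(self) -> tuple[int, ...] | None:
        return self.images[0].shape if self.images else None

    def label_simplex(self) -> np.ndarray:
        """Per-sample label distributions: soft labels if present, else one-hot."""
        if self.soft_labels is not None:
            return self.soft_labels
        onehot = np.zeros((len(self), self.n_classes), dtype=np.float32)
        if len(self):
            onehot[np.arange(len(self)), self.labels] = 1.0
        return onehot

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            source=self.source,
            soft_labels=None if self.soft_labels is None else self.soft_labels[idx],
            magnifications=None if self.magnifications is None else [self.magnifications[i] for i in idx],
            nucleus_masks=None if self.nucleus_masks is None else [self.nucleus_masks[i] for i in idx],
        )

    def as_batch(self) -> np.ndarray:
        """Stack images into a (B, 3, H, W) float32 batch."""
        if not self.images:
            return np.zeros((0, 3, 0, 0), dtype=np.float32)
        return np.stack(self.images).transpose(0, 3, 1, 2).astype(np.float32)


@dataclass
class ClassTexture:
    """Per-class appearance of the synthetic tissue."""

    blob_density: float  # nuclei per 64x64 patch
    radius_range: tuple[float, float]  # semi-axis range, px at 64 px scale
    nucleus_color: tuple[float, float, float]
    background: tuple[float, float, float] = (0.93, 0.78, 0.84)  # eosin pink


def default_textures(n_classes: int) -> list[ClassTexture]:
    """Deterministic, strongly separated per-class texture parameters.

    Density and stain darkness both increase with class index; nucleus size
    alternates so adjacent classes also differ in granularity.
    """
    textures = []
    for k in range(n_classes):
        density = 8.0 + 26.0 * k
        lo = 2.0 + 1.5 * (k % 2)
        hi = lo + 2.5
        shade = max(0.15, 0.55 - 0.12 * k)
        color = (shade * 0.6, shade * 0.45, min(1.0, shade + 0.25))
        textures.append(ClassTexture(density, (lo, hi), color))
    return textures


@dataclass
class SyntheticSpec:
    """Recipe for a reproducible synthetic image set."""

    n_classes: int = 4
    per_class: int = 25
    image_size: int = 64
    seed: int = 0
    textures: list[ClassTexture] = field(default_factory=list)
    keep_masks: bool = False

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("need at least two classes")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.per_class < 0:
            raise ConfigurationError("per_class must be >= 0")
        if not self.textures:
            self.textures = default_textures(self.n_classes)
        if len(self.textures) != self.n_classes:
            raise ConfigurationError("one texture spec per class required")


def _render_tissue(rng: np.random.Generator, size: int, tex: ClassTexture, keep_mask: bool):
    scale = size / 64.0
    img = np.empty((size, size, 3), dtype=np.float32)
    img[...] = tex.background
    img += rng.normal(0.0, 0.015, size=img.shape).astype(np.float32)
    n_blobs = rng.poisson(tex.blob_density * scale * scale)
    mask = np.zeros((size, size), dtype=bool) if keep_mask else None
    for _ in range(n_blobs):
        r = rng.uniform(0, size)
        c = rng.uniform(0, size)
        a = rng.uniform(*tex.radius_range) * scale
        b = rng.uniform(*tex.radius_range) * scale
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(r, c, a, b, shape=(size, size), rotation=theta)
        jitter = rng.normal(0, 0.04, size=3)
        img[rr, cc] = np.clip(np.asarray(tex.nucleus_color) + jitter, 0, 1)
        if mask is not None:
            mask[rr, cc] = True
    np.clip(img, 0.0, 1.0, out=img)
    return img, mask


def generate_synthetic_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Generate ``n_classes * per_class`` class-separable tissue-like images.

    Identical spec (including seed) yields bit-identical output.
    """
    images: list[np.ndarray] = []
    labels: list[int] = []
    masks: list[np.ndarray] | None = [] if spec.keep_masks else None
    root = np.random.SeedSequence(spec.seed)
    for k in range(spec.n_classes):
        for j in range(spec.per_class):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=root.entropy, spawn_key=(k, j)))
            img, mask = _render_tissue(rng, spec.image_size, spec.textures[k], spec.keep_masks)
            images.append(img)
            labels.append(k)
            if masks is not None:
                masks.append(mask)
    class_names = [f"class_{k}" for k in range(spec.n_classes)]
    return LabeledImageSet(images, np.asarray(labels), class_names, source="synthetic", nucleus_masks=masks)


# --------------------------------------------------------------------- readers


def _load_image(path: Path, image_size: int) -> np.ndarray | None:
    try:
        with Image.open(path) as im:
            im = im.convert("RGB").resize((image_size, image_size), Image.BILINEAR)
            return np.asarray(im, dtype=np.float32) / 255.0
    except Exception as exc:  # undecodable file: warn and skip
        logger.warning("skipping undecodable image %s (%s)", path, exc)
        return None


def _magnification_of(path: Path, root: Path) -> str:
    for part in path.relative_to(root).parts:
        if part.upper().endswith("X") and part[:-1].isdigit():
            return part.upper()
    return ""


def read_image_folder(root, layout: str = "flat", image_size: int = 224) -> LabeledImageSet:
    """Read a class-per-directory image tree into a :class:`LabeledImageSet`.

    ``layout='flat'`` expects ``root/<class>/<image>``; ``layout='breakhis'``
    takes the class from the top-level directory and records the
    magnification subdirectory (e.g. ``40X``) as metadata;
    ``layout='bach'`` is the flat four-class microscopy tree.  Labels are
    assigned from class directory names sorted lexicographically.
    """
    root = Path(root)
    if layout not in {"flat", "breakhis", "bach"}:
        raise ConfigurationError(f"unknown layout {layout!r}")
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if layout == "bach":
        names = {p.name.lower().replace(" ", "") for p in class_dirs}
        expected = {c.lower() for c in BACH_CLASSES}
        if names != expected:
            logger.warning("four-class layout expected directories %s, found %s", sorted(expected), sorted(names))
    images, labels, mags = [], [], []
    for label, cdir in enumerate(class_dirs):
        for path in sorted(cdir.rglob("*")):
            if path.suffix.lower() not in _IMAGE_SUFFIXES or not path.is_file():
                continue
            img = _load_image(path, image_size)
            if img is None:
                continue
            images.append(img)
            labels.append(label)
            mags.append(_magnification_of(path, root) if layout == "breakhis" else "")
    if not images:
        raise DataError(f"no decodable images under {root}")
    return LabeledImageSet(
        images,
        np.asarray(labels),
        [d.name for d in class_dirs],
        source="folder",
        magnifications=mags if layout == "breakhis" else None,
    )


def write_manifest(data: LabeledImageSet, path, filenames: list[str] | None = None) -> None:
    """Emit a CSV manifest (filepath, label, class_name, magnification)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filepath", "label", "class_name", "magnification"])
        for i, label in enumerate(data.labels):
            name = filenames[i] if filenames else f"image_{i:05d}.png"
            mag = data.magnifications[i] if data.magnifications else ""
            writer.writerow([name, int(label), data.class_names[label], mag])


def save_image_folder(data: LabeledImageSet, out_dir) -> list[str]:
    """Write the set as ``out_dir/<class>/<image>.png`` plus a manifest."""
    out_dir = Path(out_dir)
    filenames = []
    for i, (img, label) in enumerate(zip(data.images, data.labels)):
        cdir = out_dir / data.class_names[label]
        cdir.mkdir(parents=True, exist_ok=True)
        rel = f"{data.class_names[label]}/image_{i:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / rel)
        filenames.append(rel)
    write_manifest(data, out_dir / "manifest.csv", filenames)
    return filenames


# ----------------------------------------------------------------------- split


def split_train_test(
    data: LabeledImageSet,
    train_frac: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Disjoint, exhaustive train/test partition.

    Train counts are floored (per class when stratified), which keeps the
    per-class train fraction within one image of ``train_frac`` and
    guarantees a non-empty test split for any ``train_frac < 1``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(data)
    if stratified:
        train_idx: list[int] = []
        test_idx: list[int] = []
        for k in range(data.n_classes):
            members = np.flatnonzero(data.labels == k)
            if members.size == 0:
                continue
            if members.size < 2:
                raise DataError(f"class {data.class_names[k]} has fewer than 2 members; cannot stratify")
            members = rng.permutation(members)
            n_train = math.floor(members.size * train_frac)
            train_idx.extend(members[:n_train])
            test_idx.extend(members[n_train:])
        train_idx, test_idx = np.asarray(sorted(train_idx)), np.asarray(sorted(test_idx))
    else:
        perm = rng.permutation(n)
        n_train = math.floor(n * train_frac)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return data.subset(train_idx), data.subset(test_idx)
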