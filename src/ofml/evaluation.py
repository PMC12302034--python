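"""Metrics, Grad-CAM heatmaps and 2-D feature embeddings.

Metrics are accuracy, macro-averaged precision/recall/F1, one-vs-rest
macro AUC and the confusion matrix, all delegated to scikit-learn except
the per-class AUC handling (a class absent from the ground truth has an
undefined one-vs-rest AUC and is excluded from the macro with a warning).

Grad-CAM weights each channel of a tapped feature map by its spatially
averaged gradient with respect to the target-class score of the model's
final classifier, rectifies the weighted sum, min-max normalizes it and
upsamples bilinearly to the input resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score

from .autodiff import Tensor
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: np.ndarray

    def to_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def compute_metrics(y_true, y_pred, y_score) -> MetricReport:
    """Accuracy, macro precision/recall/F1, OVR-macro AUC, confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_score = np.asarray(y_score)
    if len(y_true) != len(y_pred) or len(y_true) != len(y_score):
        raise DataError("y_true, y_pred and y_score must have equal lengths")
    m = y_score.shape[1]
    labels = np.arange(m)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(cm) / cm.sum())
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    aucs = []
    for k in labels:
        positives = y_true == k
        if positives.all() or not positives.any():
            logger.warning("class %d absent from one side of y_true; excluded from macro AUC", k)
            continue
        aucs.append(roc_auc_score(positives, y_score[:, k]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    return MetricReport(accuracy, float(precision), float(recall), float(f1), auc, cm)


_TAPS = ("cnn", "mvt", "fusion-input")


def grad_cam(network, image: np.ndarray, target_class: int, tap: str = "fusion-input") -> np.ndarray:
    """Class-activation heatmap in [0, 1] at input resolution.

    ``tap`` selects the feature map: the CNN tap, the transformer tap, or
    ``fusion-input`` — the mean of the two branch maps' normalized CAMs,
    mirroring what the fusion classifier consumes.
    """
    if tap not in _TAPS:
        raise ConfigurationError(f"tap must be one of {_TAPS}")
    if not 0 <= target_class < network.num_classes:
        raise ConfigurationError(f"target_class {target_class} out of range [0, {network.num_classes})")
    h, w = image.shape[:2]
    network.eval()
    x = Tensor(image[None].transpose(0, 3, 1, 2).astype(np.float32))
    out = network(x)
    wanted = {"cnn": ["fm1"], "mvt": ["fm2"], "fusion-input": ["fm1", "fm2"]}[tap]
    maps = []
    for key in wanted:
        if key not in out:
            raise ConfigurationError(f"variant has no {key} feature map for tap={tap!r}")
        out[key].retain_grad()
        maps.append(out[key])
    score = out["pred"][0, target_class]
    network.zero_grad()
    score.backward()
    cams = [_cam_from(fm.data[0], fm.grad[0], (w, h)) for fm in maps]
    return np.mean(cams, axis=0)


def _cam_from(activation: np.ndarray, grad: np.ndarray, size_wh: tuple[int, int]) -> np.ndarray:
    weights = grad.mean(axis=(1, 2))  # spatially averaged gradients per channel
    cam = np.maximum((weights[:, None, None] * activation).sum(axis=0), 0.0)
    span = cam.max() - cam.min()
    cam = (cam - cam.min()) / span if span > 0 else np.zeros_like(cam)
    resized = Image.fromarray(cam.astype(np.float32), mode="F").resize(size_wh, Image.BILINEAR)
    return np.clip(np.asarray(resized), 0.0, 1.0)


def embed_features_2d(features: np.ndarray, labels, seed: int = 0) -> pd.DataFrame:
    """t-SNE embedding of per-sample feature vectors to a (x, y, label) table."""
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(features)
    if n < 5:
        raise DataError("need at least 5 samples for a 2-D embedding")
    if np.allclose(features.std(axis=0), 0):
        raise DataError("degenerate constant features: every sample is identical")
    perplexity = float(min(30, max(2, (n - 1) // 3)))
    tsne = TSNE(n_components=2, random_state=seed, init="pca", perplexity=perplexity)
    xy = tsne.fit_transform(features)
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "label": labels})
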