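"""Online-fusion-mutual-learning loss components.

Both backbones are supervised by a cross-entropy on their own logits and,
through *fusion pathological knowledge transfer* (FPKT), pulled toward the
fusion classifier's temperature-softened distribution with a KL divergence
scaled by T^2 (the classic distillation gradient-scale correction).  The
ensemble classifier (mean of the branch logits) has its own cross-entropy,
and *ensemble pathological knowledge transfer* (EPKT) feeds the ensemble's
softened distribution to the fusion classifier, again via KL.  Knowledge
flows only through these divergence terms: the teacher distribution in
every transfer is detached, so no gradient reaches the teacher.

The literal printed total, L_f = L1 + L2 + T^2 * L_ensemble, contains no
term that trains the fusion head; the default total therefore adds the
EPKT term and a fusion-head cross-entropy, each with weight 1.0 and each
disableable, so that a strict literal mode remains available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .autodiff import Tensor
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

EPS = 1e-12


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def soften(logits, temperature: float) -> Tensor:
    """Temperature-softened class distribution: softmax(logits / T).

    Computed via a max-shifted log-softmax, so it is stable for any finite
    logits; T -> infinity approaches the uniform distribution.
    """
    if temperature <= 0:
        raise ConfigurationError(f"temperature must be positive, got {temperature}")
    logits = _as_tensor(logits)
    return (logits * (1.0 / temperature)).softmax(axis=-1)


def cross_entropy(probs, target) -> Tensor:
    """Negative log-likelihood of ``target`` under ``probs``.

    ``target`` may be an integer class index, a vector of indices, or label
    distributions on the simplex (soft Mixup labels); the loss generalizes
    to -sum_m y_m log p_m, averaged over the batch.  Probabilities are
    clamped at 1e-12 before the log.
    """
    probs = _as_tensor(probs)
    if probs.ndim == 1:
        probs = probs.reshape(1, -1)
    batch, m = probs.shape
    target = np.asarray(target)
    if target.ndim <= 1 and np.issubdtype(target.dtype, np.integer):
        onehot = np.zeros((batch, m), dtype=np.float32)
        onehot[np.arange(batch), target.reshape(-1)] = 1.0
        target = onehot
    elif target.ndim == 1:
        target = target.reshape(1, -1)
    if (probs.data[target > 0] <= EPS).any():
        logger.warning("cross_entropy: zero probability at a supported class; clamping at %.0e", EPS)
    ll = Tensor(target.astype(np.float32)) * probs.clip_min(EPS).log()
    return -(ll.sum() * (1.0 / batch))


def kl_divergence(p, q) -> Tensor:
    """D_KL(p || q) = sum_m p_m log(p_m / q_m), batch-averaged."""
    p, q = _as_tensor(p), _as_tensor(q)
    if not (np.isfinite(p.data).all() and np.isfinite(q.data).all()):
        raise DataError("kl_divergence received non-finite inputs")
    if p.ndim == 1:
        p = p.reshape(1, -1)
        q = q.reshape(1, -1)
    batch = p.shape[0]
    ratio = p.clip_min(EPS).log() - q.clip_min(EPS).log()
    return (p * ratio).sum() * (1.0 / batch)


@dataclass
class LossBundle:
    """Every itemized loss term of one mini-batch (scalar tensors)."""

    L_net1: Tensor | None = None
    L_FPKT1: Tensor | None = None
    L1: Tensor | None = None
    L_net2: Tensor | None = None
    L_FPKT2: Tensor | None = None
    L2: Tensor | None = None
    L_ensemble: Tensor | None = None
    L_EPKT: Tensor | None = None
    L_fusion_ce: Tensor | None = None
    L_f: Tensor | None = None

    def to_floats(self) -> dict[str, float]:
        return {
            f.name: float(getattr(self, f.name).data)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }

    def first_nonfinite(self) -> str | None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value is not None and not np.isfinite(value.data).all():
                return f.name
        return None


def branch_total(branch_logits: Tensor, target, fusion_logits: Tensor, temperature: float):
    """Per-branch loss triple (L_net, L_FPKT, L_total).

    L_net is the cross-entropy of the branch's own T=1 distribution;
    L_FPKT is KL(branch softened || fusion softened) with the fusion
    classifier as a detached teacher; the total is L_net + T^2 * L_FPKT.
    """
    l_net = cross_entropy(soften(branch_logits, 1.0), target)
    l_fpkt = kl_divergence(soften(branch_logits, temperature), soften(fusion_logits.detach(), temperature))
    total = l_net + l_fpkt * (temperature**2)
    return l_net, l_fpkt, total


def global_total(
    bundle: LossBundle,
    temperature: float,
    w_epkt: float = 1.0,
    w_fusion_ce: float = 1.0,
) -> Tensor:
    """Total training loss.

    L_f = L1 + L2 + T^2 * L_ensemble + w_epkt * L_EPKT
          + w_fusion_ce * L_fusion_ce,
    where absent components contribute zero.  Setting both weights to zero
    reproduces the literal three-term total.
    """
    total = Tensor(np.zeros(()))
    if bundle.L1 is not None:
        total = total + bundle.L1
    if bundle.L2 is not None:
        total = total + bundle.L2
    if bundle.L_ensemble is not None:
        total = total + bundle.L_ensemble * (temperature**2)
    if bundle.L_EPKT is not None and w_epkt:
        total = total + bundle.L_EPKT * w_epkt
    if bundle.L_fusion_ce is not None and w_fusion_ce:
        total = total + bundle.L_fusion_ce * w_fusion_ce
    return total


def assemble_bundle(
    target,
    temperature: float,
    logits1: Tensor | None = None,
    logits2: Tensor | None = None,
    fusion_logits: Tensor | None = None,
    ensemble: Tensor | None = None,
    w_epkt: float = 1.0,
    w_fusion_ce: float = 1.0,
) -> LossBundle:
    """Build the full loss bundle for whichever heads a variant possesses.

    Branches distill from the fusion classifier only when it exists;
    otherwise they fall back to plain cross-entropy supervision.  EPKT is
    computed only when both the ensemble and fusion heads are present.
    """
    bundle = LossBundle()
    for idx, logits in ((1, logits1), (2, logits2)):
        if logits is None:
            continue
        if fusion_logits is not None:
            l_net, l_fpkt, total = branch_total(logits, target, fusion_logits, temperature)
            setattr(bundle, f"L_net{idx}", l_net)
            setattr(bundle, f"L_FPKT{idx}", l_fpkt)
        else:
            l_net = cross_entropy(soften(logits, 1.0), target)
            setattr(bundle, f"L_net{idx}", l_net)
            total = l_net
        setattr(bundle, f"L{idx}", total)
    if ensemble is not None:
        bundle.L_ensemble = cross_entropy(soften(ensemble, 1.0), target)
        if fusion_logits is not None and w_epkt:
            bundle.L_EPKT = kl_divergence(
                soften(ensemble.detach(), temperature), soften(fusion_logits, temperature)
            )
    if fusion_logits is not None and w_fusion_ce:
        bundle.L_fusion_ce = cross_entropy(soften(fusion_logits, 1.0), target)
    bundle.L_f = global_total(bundle, temperature, w_epkt=w_epkt, w_fusion_ce=w_fusion_ce)
    return bundle
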