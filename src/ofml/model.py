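"""The fitted-model layer: network assembly, joint training, results.

:class:`OFMLModel` is built from a :class:`~ofml.data.LabeledImageSet` and
a :class:`~ofml.config.TrainConfig`; :meth:`OFMLModel.fit` jointly
optimizes both backbones and the fusion head — one backward pass on the
summed total loss per mini-batch, a single Adam step updating every
parameter group simultaneously — and returns an :class:`OFMLResults`
carrying the per-epoch loss/metric history, prediction methods, metrics,
Grad-CAM and 2-D feature embeddings.

Ablation variants reproduce the component study: A = CNN alone, B = plain
(single-view) transformer alone, C = both branches without multi-view
fusion or heads, D = C with multi-view encoding, E = D + ensemble
classifier, F = D + fusion classifier, G = F + E, and "full" = G + Mixup;
AFC1/2/3 move the tapped feature-map pair to residual stage / encoder
layer 1, 2 or 3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor, nn, optim
from .augment import MixupConfig, expand_dataset
from .cnn import ResNetBranch
from .config import TrainConfig, MVTSettings
from .data import LabeledImageSet
from .exceptions import ConfigurationError, DataError, DivergenceError
from .heads import FusionHead, ensemble_logits
from .losses import LossBundle, assemble_bundle
from .mvt import MultiViewTransformer


@dataclass(frozen=True)
class VariantSpec:
    use_cnn: bool
    use_mvt: bool
    multi_view: bool
    use_ensemble: bool
    use_fusion: bool
    use_mixup: bool
    tap_pair: int | None = None  # AFC ablations: tap stage/layer index


VARIANT_SPECS: dict[str, VariantSpec] = {
    "A": VariantSpec(True, False, False, False, False, False),
    "B": VariantSpec(False, True, False, False, False, False),
    "C": VariantSpec(True, True, False, False, False, False),
    "D": VariantSpec(True, True, True, False, False, False),
    "E": VariantSpec(True, True, True, True, False, False),
    "F": VariantSpec(True, True, True, False, True, False),
    "G": VariantSpec(True, True, True, True, True, False),
    "full": VariantSpec(True, True, True, True, True, True),
    "AFC1": VariantSpec(True, True, True, False, True, False, tap_pair=1),
    "AFC2": VariantSpec(True, True, True, False, True, False, tap_pair=2),
    "AFC3": VariantSpec(True, True, True, False, True, False, tap_pair=3),
}


class OFMLNetwork(nn.Module):
    """Both backbones plus whichever heads the variant includes."""

    def __init__(self, num_classes: int, config: TrainConfig, spec: VariantSpec, rng: np.random.Generator):
        super().__init__()
        if not (spec.use_cnn or spec.use_mvt):
            raise ConfigurationError("a variant needs at least one backbone")
        if spec.use_fusion and not (spec.use_cnn and spec.use_mvt):
            raise ConfigurationError("the fusion classifier needs both backbones' feature maps")
        if spec.use_ensemble and not (spec.use_cnn and spec.use_mvt):
            raise ConfigurationError("the ensemble classifier needs both branch logits")
        self.num_classes = num_classes
        self.spec = spec
        if spec.use_cnn:
            tap = spec.tap_pair if spec.tap_pair is not None else config.cnn.tap_stage
            self.cnn = ResNetBranch(
                num_classes,
                rng,
                block_counts=config.cnn.block_counts,
                base_width=config.cnn.base_width,
                tap_stage=tap,
                small_stem=config.cnn.small_stem,
            )
        else:
            self.cnn = None
        if spec.use_mvt:
            m: MVTSettings = config.mvt
            view_dims = m.view_dims if spec.multi_view else (m.global_dim,)
            self.mvt = MultiViewTransformer(
                num_classes,
                config.image_size,
                rng,
                patch_size=m.patch_size,
                view_dims=view_dims,
                layers_per_view=m.layers_per_view,
                global_dim=m.global_dim,
                global_depth=m.global_depth,
                heads=m.heads,
                tap_layer=spec.tap_pair if spec.tap_pair is not None else m.tap_layer,
            )
        else:
            self.mvt = None
        if spec.use_fusion:
            self.fusion = FusionHead(self.cnn.tap_channels, config.mvt.global_dim, num_classes, rng)
        else:
            self.fusion = None

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        if self.cnn is not None:
            b1 = self.cnn(x)
            out["logits1"], out["fm1"] = b1.logits, b1.feature_map
        if self.mvt is not None:
            b2 = self.mvt(x)
            out["logits2"], out["fm2"] = b2.logits, b2.feature_map
        if self.spec.use_ensemble:
            out["ensemble"] = ensemble_logits(out["logits1"], out["logits2"])
        if self.fusion is not None:
            out["fusion"] = self.fusion(out["fm1"], out["fm2"])
        out["pred"] = self._prediction_logits(out)
        return out

    def _prediction_logits(self, out: dict[str, Tensor]) -> Tensor:
        """Classification comes from the fusion head when present, then the
        ensemble, then the (mean of the) branch logits."""
        if "fusion" in out:
            return out["fusion"]
        if "ensemble" in out:
            return out["ensemble"]
        if "logits1" in out and "logits2" in out:
            return ensemble_logits(out["logits1"], out["logits2"])
        return out.get("logits1", out.get("logits2"))


def build_ablation_variant(
    name: str, config: TrainConfig, num_classes: int, seed: int | None = None
) -> OFMLNetwork:
    """Construct the component-study variant ``name`` (A..G, full, AFC1-3)."""
    if name not in VARIANT_SPECS:
        raise ConfigurationError(f"unknown variant {name!r}; choose from {sorted(VARIANT_SPECS)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return OFMLNetwork(num_classes, config, VARIANT_SPECS[name], rng)


class OFMLModel:
    """Dual-branch mutual-learning classifier bound to a training set.

    Parameters
    ----------
    data
        Training images (hard or Mixup-soft labels).
    config
        Full training configuration; ``config.variant`` selects the
        architecture.
    test_data
        Optional held-out split, evaluated every ``config.eval_every``
        epochs during :meth:`fit`.
    """

    def __init__(self, data: LabeledImageSet, config: TrainConfig | None = None, test_data: LabeledImageSet | None = None):
        if data.n_classes < 2:
            raise DataError("training data must have at least 2 classes")
        self.config = config or TrainConfig()
        if data.image_shape is not None and data.image_shape[0] != self.config.image_size:
            raise DataError(
                f"images are {data.image_shape[0]} px but config.image_size is {self.config.image_size}"
            )
        self.data = data
        self.test_data = test_data
        self.network = build_ablation_variant(self.config.variant, self.config, data.n_classes)

    @classmethod
    def from_folder(cls, root, layout: str = "flat", config: TrainConfig | None = None, **kwargs) -> "OFMLModel":
        from .data import read_image_folder, split_train_test

        config = config or TrainConfig()
        full = read_image_folder(root, layout=layout, image_size=config.image_size)
        train, test = split_train_test(full, config.train_frac, seed=config.seed)
        return cls(train, config, test_data=test, **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self, epochs: int | None = None, out_dir=None, progress: bool = False) -> "OFMLResults":
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        seq = np.random.SeedSequence(cfg.seed)
        shuffle_rng = np.random.default_rng(np.random.SeedSequence(entropy=seq.entropy, spawn_key=(1,)))

        train = self.data
        spec = VARIANT_SPECS[cfg.variant]
        if spec.use_mixup and cfg.mixup.enabled and len(train):
            mix_seed = int(np.random.default_rng(
                np.random.SeedSequence(entropy=seq.entropy, spawn_key=(2,))
            ).integers(2**31))
            train = expand_dataset(
                train,
                MixupConfig(
                    alpha=cfg.mixup.alpha,
                    factor=cfg.mixup.factor,
                    seed=mix_seed,
                    within_class=cfg.mixup.within_class,
                ),
            )

        images = train.as_batch()
        targets = train.label_simplex()
        hard = train.labels
        n = len(train)
        w_epkt, w_fce = cfg.effective_loss_weights
        optimizer = optim.Adam(
            self.network.parameters(),
            lr=cfg.learning_rate,
            beta1=cfg.adam_beta1,
            beta2=cfg.adam_beta2,
            weight_decay=cfg.weight_decay,
        )

        rows: list[dict] = []
        self.network.train()
        for epoch in range(1, epochs + 1):
            order = shuffle_rng.permutation(n)
            sums: dict[str, float] = {}
            correct = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = Tensor(images[idx])
                out = self.network(batch)
                bundle = assemble_bundle(
                    targets[idx],
                    cfg.temperature,
                    logits1=out.get("logits1"),
                    logits2=out.get("logits2"),
                    fusion_logits=out.get("fusion"),
                    ensemble=out.get("ensemble"),
                    w_epkt=w_epkt,
                    w_fusion_ce=w_fce,
                )
                bad = bundle.first_nonfinite()
                if bad is not None:
                    raise DivergenceError(f"non-finite loss component {bad} at epoch {epoch}")
                self.network.zero_grad()
                bundle.L_f.backward()
                optimizer.step()
                for key, value in bundle.to_floats().items():
                    sums[key] = sums.get(key, 0.0) + value * len(idx)
                correct += int((out["pred"].data.argmax(axis=1) == hard[idx]).sum())
            row = {"epoch": epoch, "train_accuracy": correct / n}
            row.update({k: v / n for k, v in sums.items()})
            if cfg.eval_every and self.test_data is not None and epoch % cfg.eval_every == 0:
                row["test_accuracy"] = self._quick_accuracy(self.test_data)
            rows.append(row)
            if progress:
                print(f"epoch {epoch:4d}  L_f={row.get('L_f', float('nan')):.4f}  "
                      f"train_acc={row['train_accuracy']:.3f}")
            if out_dir and cfg.checkpoint_every and epoch % cfg.checkpoint_every == 0:
                self._save_checkpoint(Path(out_dir) / f"checkpoint_epoch{epoch:04d}")
        self.network.eval()
        history = pd.DataFrame(rows)
        return OFMLResults(self, history)

    def _quick_accuracy(self, data: LabeledImageSet) -> float:
        pred = predict(self.network, data.as_batch())["labels"]
        return float((pred == data.labels).mean())

    def _save_checkpoint(self, prefix: Path) -> None:
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez(str(prefix) + ".npz", **self.network.state_dict())
        payload = {
            "config": self.config.model_dump(mode="json"),
            "class_names": self.data.class_names,
        }
        import yaml

        (Path(str(prefix) + ".yaml")).write_text(yaml.safe_dump(payload, sort_keys=False))


def predict(network: OFMLNetwork, batch: np.ndarray, batch_size: int = 64) -> dict[str, np.ndarray]:
    """Class probabilities (softmax at T=1 of the prediction head) and labels.

    Also exposes the per-branch and ensemble probabilities that exist for
    the variant, for the component-study harness.
    """
    was_training = network.training
    network.eval()
    pieces: dict[str, list[np.ndarray]] = {}
    for start in range(0, len(batch), batch_size):
        out = network(Tensor(batch[start : start + batch_size]))
        for key in ("pred", "logits1", "logits2", "ensemble", "fusion"):
            if key in out and out[key] is not None:
                pieces.setdefault(key, []).append(out[key].data)
    network.train(was_training)
    result: dict[str, np.ndarray] = {}
    for key, chunks in pieces.items():
        logits = np.concatenate(chunks, axis=0)
        shifted = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(shifted)
        result[f"{key}_probs" if key != "pred" else "probs"] = exp / exp.sum(axis=1, keepdims=True)
    result["labels"] = result["probs"].argmax(axis=1)
    return result


class OFMLResults:
    """Estimates and diagnostics of a fitted :class:`OFMLModel`."""

    def __init__(self, model: OFMLModel, history: pd.DataFrame):
        self.model = model
        self.network = model.network
        self.config = model.config
        self.history = history

    # ------------------------------------------------------------- predict
    def predict(self, data: LabeledImageSet | np.ndarray, batch_size: int = 64) -> dict[str, np.ndarray]:
        batch = data.as_batch() if isinstance(data, LabeledImageSet) else np.asarray(data, dtype=np.float32)
        expected = self.config.image_size
        if batch.shape[-1] != expected or batch.shape[-2] != expected:
            raise DataError(f"images are {batch.shape[-2]}x{batch.shape[-1]} but the model was configured for {expected} px")
        return predict(self.network, batch, batch_size=batch_size)

    def evaluate(self, data: LabeledImageSet) -> "MetricReport":
        from .evaluation import compute_metrics

        pred = self.predict(data)
        return compute_metrics(data.labels, pred["labels"], pred["probs"])

    def fused_features(self, data: LabeledImageSet, batch_size: int = 64) -> np.ndarray:
        """The fusion head's input: pooled, concatenated branch feature maps."""
        if self.network.fusion is None:
            raise ConfigurationError("this variant has no fusion head")
        batch = data.as_batch()
        chunks = []
        self.network.eval()
        for start in range(0, len(batch), batch_size):
            out = self.network(Tensor(batch[start : start + batch_size]))
            p1 = out["fm1"].data.mean(axis=(2, 3))
            p2 = out["fm2"].data.mean(axis=(2, 3))
            chunks.append(np.concatenate([p1, p2], axis=1))
        return np.concatenate(chunks, axis=0)

    def grad_cam(self, image: np.ndarray, target_class: int, tap: str = "fusion-input") -> np.ndarray:
        from .evaluation import grad_cam

        return grad_cam(self.network, image, target_class, tap=tap)

    def embed_2d(self, data: LabeledImageSet, seed: int = 0) -> pd.DataFrame:
        from .evaluation import embed_features_2d

        return embed_features_2d(self.fused_features(data), data.labels, seed=seed)

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        final = self.history.iloc[-1].to_dict() if len(self.history) else {}
        lines = [
            "Online Fusion Mutual Learning — fit summary",
            "=" * 46,
            f"variant:            {self.config.variant}",
            f"classes:            {self.model.data.n_classes} ({', '.join(self.model.data.class_names)})",
            f"training images:    {len(self.model.data)}"
            + (f" (x{self.config.mixup.factor} Mixup)" if VARIANT_SPECS[self.config.variant].use_mixup and self.config.mixup.enabled else ""),
            f"image size:         {self.config.image_size} px",
            f"parameters:         {self.network.num_parameters():,}",
            f"epochs completed:   {len(self.history)}",
            f"temperature T:      {self.config.temperature}",
        ]
        if final:
            lines.append("-" * 46)
            for key in ("L_net1", "L_FPKT1", "L1", "L_net2", "L_FPKT2", "L2",
                        "L_ensemble", "L_EPKT", "L_fusion_ce", "L_f"):
                if key in final and np.isfinite(final.get(key, np.nan)):
                    lines.append(f"final {key:12s}  {final[key]:.4f}")
            lines.append(f"final train accuracy  {final['train_accuracy']:.4f}")
            if "test_accuracy" in final and np.isfinite(final["test_accuracy"]):
                lines.append(f"final test accuracy   {final['test_accuracy']:.4f}")
        return "\n".join(lines)

    # ---------------------------------------------------------- persistence
    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez(str(prefix) + ".npz", **self.network.state_dict())
        import yaml

        payload = {
            "config": self.config.model_dump(mode="json"),
            "class_names": self.model.data.class_names,
        }
        Path(str(prefix) + ".yaml").write_text(yaml.safe_dump(payload, sort_keys=False))
        self.history.to_csv(str(prefix) + "_history.csv", index=False)

    @classmethod
    def load(cls, prefix) -> "OFMLResults":
        import yaml

        payload = yaml.safe_load(Path(str(prefix) + ".yaml").read_text())
        config = TrainConfig.model_validate(payload["config"])
        class_names = payload["class_names"]
        placeholder = LabeledImageSet([], np.asarray([], dtype=int), class_names, source="folder")
        model = OFMLModel.__new__(OFMLModel)
        model.config = config
        model.data = placeholder
        model.test_data = None
        model.network = build_ablation_variant(config.variant, config, len(class_names))
        with np.load(str(prefix) + ".npz") as state:
            model.network.load_state_dict({k: state[k] for k in state.files})
        model.network.eval()
        history_path = Path(str(prefix) + "_history.csv")
        history = pd.read_csv(history_path) if history_path.exists() else pd.DataFrame()
        return cls(model, history)

    def plot_history(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        for col in self.history.columns:
            if col.startswith("L"):
                ax1.plot(self.history["epoch"], self.history[col], label=col)
        ax1.set_xlabel("epoch"); ax1.set_ylabel("loss"); ax1.legend(fontsize=7)
        ax2.plot(self.history["epoch"], self.history["train_accuracy"], label="train")
        if "test_accuracy" in self.history:
            ax2.plot(self.history["epoch"], self.history["test_accuracy"], label="test")
        ax2.set_xlabel("epoch"); ax2.set_ylabel("accuracy"); ax2.legend()
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
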