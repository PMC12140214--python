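"""Classifier fine-tuning: tanh-softmax head, label-smoothing loss,
augmentation, and a warm-up training schedule with a frozen backbone."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ..openset import ProbabilityVector
from .augment import AugmentConfig, augment, resize_image
from .nn import (
    Adam,
    ClassifierModel,
    TanhSoftmaxHead,
    TinyCNNBackbone,
    softmax,
)

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "ClassifierModel",
    "TinyCNNBackbone",
    "TanhSoftmaxHead",
    "augment",
    "build_head",
    "label_smoothing_loss",
    "train_classifier",
    "predict",
    "resize_image",
]

logger = logging.getLogger(__name__)

LOG_CLAMP = 1e-12


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    The defaults mirror the reference regime: batch 64, five epochs after a
    one-epoch frozen-backbone warm-up, Adam at 0.003, label-smoothing
    cross-entropy, and an augmentation probability of 0.8 on 224x224
    inputs. The ``tiny_cnn`` backbone trains offline on a CPU; ``external``
    is a hook for a user-supplied pretrained feature extractor.
    """

    batch_size: int = 64
    epochs: int = 5
    learning_rate: float = 0.003
    warmup_epochs: int = 1
    label_smoothing_eps: float = 0.1
    augment_prob: float = 0.8
    image_size: int = 224
    seed: int = 0
    backbone_name: str = "tiny_cnn"
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    early_stop_patience: Optional[int] = None  # plateau stop on val loss

    def __post_init__(self) -> None:
        if min(self.batch_size, self.image_size) < 1:
            raise ValueError("batch_size and image_size must be positive")
        if self.epochs < 0 or self.warmup_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.epochs + self.warmup_epochs < 1:
            raise ValueError("at least one total epoch is required")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.augment_prob <= 1.0):
            raise ValueError("augment_prob must lie in [0, 1]")
        self.augment = replace(self.augment, prob=self.augment_prob)


def build_head(feature_dim: int, n_classes: int,
               rng: Optional[np.random.Generator] = None) -> TanhSoftmaxHead:
    """Linear -> tanh -> softmax head with one node per class."""
    return TanhSoftmaxHead(feature_dim, n_classes, rng=rng)


def label_smoothing_loss(
    probs: np.ndarray, true_idx: np.ndarray | int, eps: float
) -> float:
    """Label-smoothing cross-entropy against q = (1-eps)*onehot + eps/n.

    Probabilities are clamped at 1e-12 inside the log for numeric safety
    (the tanh head cannot produce exact zeros anyway).
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    true_idx = np.atleast_1d(np.asarray(true_idx, dtype=int))
    n = probs.shape[1]
    q = np.full_like(probs, eps / n)
    q[np.arange(len(probs)), true_idx] += 1.0 - eps
    logp = np.log(np.clip(probs, LOG_CLAMP, 1.0))
    return float(-(q * logp).sum(axis=1).mean())


def _smoothed_targets(true_idx: np.ndarray, n: int, eps: float) -> np.ndarray:
    q = np.full((len(true_idx), n), eps / n)
    q[np.arange(len(true_idx)), true_idx] += 1.0 - eps
    return q


def _prepare_images(images: Sequence[np.ndarray], size: int) -> np.ndarray:
    return np.stack([resize_image(np.asarray(im, dtype=np.float64), size)
                     for im in images])


def train_classifier(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    cfg: TrainConfig,
    class_names: Optional[list[str]] = None,
    val_images: Optional[Sequence[np.ndarray]] = None,
    val_labels: Optional[Sequence[str]] = None,
) -> tuple[ClassifierModel, list[dict]]:
    """Train the classifier with a frozen-backbone warm-up epoch.

    During the first ``warmup_epochs`` epochs only the head parameters are
    updated; the backbone stays bit-identical. All subsequent epochs update
    every parameter. Returns the model and a per-epoch history of train
    (and, when a validation set is given, validation) loss.
    """
    if class_names is None:
        class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise TrainingError("need at least 2 classes in the training data")
    missing = set(class_names) - set(labels)
    if missing:
        raise TrainingError(f"classes missing from training data: {sorted(missing)}")

    idx_of = {c: i for i, c in enumerate(class_names)}
    y = np.array([idx_of[l] for l in labels])
    n = len(class_names)

    rng = np.random.default_rng(cfg.seed)
    if cfg.backbone_name != "tiny_cnn":
        raise TrainingError(
            f"backbone {cfg.backbone_name!r} is not available offline; "
            "use 'tiny_cnn' or plug in an external feature extractor"
        )
    backbone = TinyCNNBackbone(rng, input_size=cfg.image_size)
    head = build_head(backbone.feature_dim, n, rng)
    model = ClassifierModel(backbone, head, class_names)
    optimizer = Adam(cfg.learning_rate)

    x_base = _prepare_images(images, cfg.image_size)
    has_val = val_images is not None and len(val_images) > 0
    if has_val:
        x_val = _prepare_images(val_images, cfg.image_size)
        y_val = np.array([idx_of[l] for l in val_labels])
    else:
        if val_images is not None:
            logger.warning("empty validation set; no validation curve")

    total_epochs = cfg.warmup_epochs + cfg.epochs
    history: list[dict] = []
    best_val = np.inf
    stale = 0

    for epoch in range(total_epochs):
        frozen = epoch < cfg.warmup_epochs
        order = rng.permutation(len(x_base))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            if cfg.augment_prob > 0:
                xb = np.stack([
                    augment(x_base[i], rng, cfg.augment, cfg.image_size)
                    for i in batch
                ])
            else:
                xb = x_base[batch]
            yb = y[batch]

            probs = model.forward(xb)
            loss = label_smoothing_loss(probs, yb, cfg.label_smoothing_eps)
            epoch_losses.append(loss)

            q = _smoothed_targets(yb, n, cfg.label_smoothing_eps)
            dpre = (probs - q) / len(batch)

            for p in head.params:
                p.zero_grad()
            if not frozen:
                for p in backbone.params:
                    p.zero_grad()

            dfeat = head.backward(dpre)
            if frozen:
                optimizer.step(head.params)
            else:
                backbone.backward(dfeat)
                optimizer.step(head.params + backbone.params)

        record = {
            "epoch": epoch + 1,
            "phase": "warmup" if frozen else "train",
            "train_loss": float(np.mean(epoch_losses)),
        }
        if has_val:
            val_probs = model.predict_proba(x_val)
            record["val_loss"] = label_smoothing_loss(
                val_probs, y_val, cfg.label_smoothing_eps
            )
        history.append(record)
        logger.info(
            "epoch=%d phase=%s train_loss=%.4f val_loss=%s",
            record["epoch"], record["phase"], record["train_loss"],
            f"{record['val_loss']:.4f}" if "val_loss" in record else "n/a",
        )

        if cfg.early_stop_patience is not None and has_val and not frozen:
            if record["val_loss"] < best_val - 1e-6:
                best_val = record["val_loss"]
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    logger.info("validation loss plateaued; stopping early")
                    break

    return model, history


def predict(model: ClassifierModel, images: Sequence[np.ndarray]) -> list[ProbabilityVector]:
    """One probability vector per crop, resized to the model's input size."""
    x = _prepare_images(images, model.backbone.input_size)
    probs = model.predict_proba(x)
    return [ProbabilityVector(p=row, class_names=model.class_names) for row in probs]
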