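"""Supervised training of either architecture.

The optimization recipe follows the study conditions: Adam on a softmax
cross-entropy objective with a batch of 60 samples and an initial learning
rate of 1e-5 over a long fixed epoch budget.  Desk-scale runs shrink the
epoch count and raise the learning rate accordingly (both are config
fields).  Every source of randomness -- parameter initialisation, batch
shuffling, dropout -- is driven by explicit seeds, so a run is
bit-reproducible on one machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = ["TrainConfig", "TrainingHistory", "train", "predict"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 60
    epochs: int = 5000
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    class_weights: bool = False       # inverse-frequency weights in the loss
    early_stopping: bool = False
    patience: int = 50

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def to_jsonl(self) -> str:
        lines = []
        for i, l in enumerate(self.loss):
            entry = {"epoch": i + 1, "loss": l, "train_acc": self.train_acc[i]}
            if self.val_acc:
                entry["val_acc"] = self.val_acc[i]
            lines.append(json.dumps(entry))
        return "\n".join(lines)


def _inverse_frequency_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(y, minlength=n_classes).astype(np.float64)
    w = y.size / (n_classes * np.maximum(counts, 1.0))
    return w


def train(model, X, y, cfg: TrainConfig, mask=None, X_val=None, y_val=None,
          mask_val=None):
    """Train ``model`` in place; returns a :class:`TrainingHistory`.

    ``X`` is a stacked feature batch (``PaddedBatch.tensors``) and ``y``
    integer class labels.  With ``cfg.early_stopping`` the loop stops once
    validation accuracy has not improved for ``cfg.patience`` epochs
    (off by default: the reference recipe trains a fixed epoch count).
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] != y.size:
        raise ValueError("one label per sample required")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain at least two classes")
    n_classes = model.cfg.n_classes
    weights = _inverse_frequency_weights(y, n_classes) if cfg.class_weights else None

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory()
    best_val, since_best = -np.inf, 0

    for epoch in range(cfg.epochs):
        model.train_mode(True)
        order = rng.permutation(X.shape[0])
        epoch_losses = []
        correct = 0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = X[idx]
            mb = None if mask is None else np.asarray(mask)[idx]
            logits = model(xb, mask=mb)
            loss = nn.softmax_cross_entropy(logits, y[idx], weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}; lower the learning "
                    "rate or check the input features"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * idx.size)
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history.loss.append(float(np.sum(epoch_losses) / order.size))
        history.train_acc.append(correct / order.size)
        if X_val is not None:
            _, val_pred = predict(model, X_val, mask=mask_val)
            val_acc = float(np.mean(val_pred == np.asarray(y_val)))
            history.val_acc.append(val_acc)
            if cfg.early_stopping:
                if val_acc > best_val:
                    best_val, since_best = val_acc, 0
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
    model.train_mode(False)
    return history


def predict(model, X, mask=None, batch_size: int = 256):
    """Class probabilities and argmax labels (ties break toward class 0).

    Inference runs with batch-norm statistics frozen and dropout off, so a
    batch of one equals the corresponding row of a larger batch.
    """
    X = np.asarray(X, dtype=np.float32)
    model.train_mode(False)
    probs = []
    for start in range(0, X.shape[0], batch_size):
        xb = X[start:start + batch_size]
        mb = None if mask is None else np.asarray(mask)[start:start + batch_size]
        logits = model(xb, mask=mb)
        probs.append(nn.softmax(logits.data.astype(np.float64), axis=1))
    probs = np.concatenate(probs, axis=0) if probs else np.empty((0, model.cfg.n_classes))
    # argmax with ties toward the lower class index
    labels = np.array([int(np.flatnonzero(row == row.max())[0]) for row in probs])
    return probs, labels
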