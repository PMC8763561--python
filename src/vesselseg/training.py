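"""Training loop: Adam + binary cross-entropy with plateau LR decay.

The recipe follows the published setup: BCE loss, Adam, learning rate
initialised at 0.1 and divided by 10 whenever the validation loss stops
improving (patience 1 epoch, minimum improvement 1e-4), batch size 8
for DRIVE-sized runs and 16 for CHASE-sized runs, and the checkpointed
model is the one with the lowest validation loss.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import nn
from .nn import functional as F
from .patches import PatchRecord

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "bce_loss", "train",
           "patches_to_arrays", "pixel_accuracy"]


class DataError(ValueError):
    pass


@dataclasses.dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults = published recipe)."""

    lr0: float = 0.1
    plateau_factor: float = 0.1
    plateau_patience: int = 1  # epochs without val-loss improvement
    min_delta: float = 1e-4  # improvement below this counts as "unchanged"
    lr_floor: float = 1e-6
    batch_size: int = 8  # DRIVE preset; CHASE uses 16
    max_epochs: int = 50
    seed: int = 0


@dataclasses.dataclass
class TrainHistory:
    train_loss: list = dataclasses.field(default_factory=list)
    val_loss: list = dataclasses.field(default_factory=list)
    val_accuracy: list = dataclasses.field(default_factory=list)
    lr: list = dataclasses.field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]

    def to_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss", "val_accuracy", "lr"])
            for i in range(len(self.train_loss)):
                w.writerow([i, self.train_loss[i], self.val_loss[i],
                            self.val_accuracy[i], self.lr[i]])


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy  -[t log p + (1-t) log(1-p)].

    Predictions outside (0, 1) are clamped to [eps, 1-eps] and a warning
    is logged, rather than raising.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.min() <= 0.0 or pred.max() >= 1.0:
        logger.warning("bce_loss: predictions outside (0,1) clamped to eps")
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-(target * np.log(p) + (1.0 - target) * np.log1p(-p)).mean())


def pixel_accuracy(pred: np.ndarray, target: np.ndarray,
                   threshold: float = 0.5) -> float:
    return float(((np.asarray(pred) >= threshold)
                  == (np.asarray(target) > 0.5)).mean())


def patches_to_arrays(records: list[PatchRecord]):
    """Stack patch records into (N,1,s,s) image and label arrays."""
    x = np.stack([r.image_patch for r in records])[:, None].astype(np.float64)
    y = np.stack([r.label_patch for r in records])[:, None].astype(np.float64)
    return x, y


def _evaluate(model, x, y, batch_size: int):
    model.eval()
    losses, accs, n = [], [], []
    with nn.no_grad():
        for s in range(0, len(x), batch_size):
            xb, yb = x[s:s + batch_size], y[s:s + batch_size]
            out = model(nn.as_tensor(xb)).data
            losses.append(bce_loss(out, yb))
            accs.append(pixel_accuracy(out, yb))
            n.append(len(xb))
    w = np.asarray(n) / sum(n)
    model.train()
    return float(np.dot(losses, w)), float(np.dot(accs, w))


def train(model, train_patches, val_patches, config: TrainConfig | None = None):
    """Optimise ``model`` on patch records; returns (best weights, history).

    The learning rate is multiplied by ``plateau_factor`` whenever the
    validation loss fails to improve by at least ``min_delta`` for
    ``plateau_patience`` consecutive epochs (never below ``lr_floor``);
    the returned weights are those of the minimum-validation-loss epoch
    and are also loaded back into ``model``.
    """
    config = config or TrainConfig()
    if not train_patches or not val_patches:
        raise DataError("train and validation sets must be non-empty")
    if train_patches and isinstance(train_patches[0], PatchRecord):
        x_tr, y_tr = patches_to_arrays(train_patches)
        x_va, y_va = patches_to_arrays(val_patches)
    else:  # pre-stacked (x, y) pairs
        x_tr, y_tr = train_patches
        x_va, y_va = val_patches

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.lr0)
    history = TrainHistory()
    best_state = model.state_dict()
    best_loss = np.inf  # strict argmin -> checkpoint
    plateau_ref = np.inf  # min_delta-gated reference -> LR schedule
    stall = 0

    model.train()
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_losses, counts = [], []
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            optimizer.zero_grad()
            out = model(nn.as_tensor(x_tr[idx]))
            loss = F.binary_cross_entropy(out, y_tr[idx])
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
            counts.append(len(idx))
        train_loss = float(np.dot(epoch_losses, np.asarray(counts) / sum(counts)))
        val_loss, val_acc = _evaluate(model, x_va, y_va, config.batch_size)

        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.lr.append(optimizer.lr)
        logger.info("epoch %d: train %.4f val %.4f acc %.4f lr %.2g",
                    epoch, train_loss, val_loss, val_acc, optimizer.lr)

        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
        if val_loss < plateau_ref - config.min_delta:
            plateau_ref = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau_patience:
                optimizer.lr = max(optimizer.lr * config.plateau_factor,
                                   config.lr_floor)
                stall = 0

    model.load_state_dict(best_state)
    model.eval()
    return best_state, history
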