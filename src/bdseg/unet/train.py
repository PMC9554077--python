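"""Training loop, learning-rate schedule, and early stopping.

Schedule semantics: Adam; if the validation loss does not improve for
``lr_patience_epochs`` epochs, the learning rate is multiplied by
``lr_factor`` (floored at ``lr_floor``); training stops after
``early_stop_epochs`` epochs without improvement.  The best model by
validation loss is kept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .model import UNet3D, UNetConfig

__all__ = ["TrainState", "LRSchedule", "dice_loss", "bce_loss", "train_unet"]

_EPS = 1e-7


@dataclass
class TrainState:
    epoch: int = 0
    best_val_loss: float = np.inf
    best_epoch: int = -1
    epochs_since_improvement: int = 0
    lr: float = 1e-3
    stopped_early: bool = False
    history: List[dict] = field(default_factory=list)
    best_params: Optional[list] = None


class LRSchedule:
    """Patience-based multiplicative decay with a floor, plus early stop."""

    def __init__(self, lr_initial: float, factor: float, patience: int,
                 floor: float, early_stop: int):
        self.lr = lr_initial
        self.factor = factor
        self.patience = patience
        self.floor = floor
        self.early_stop = early_stop
        self.best = np.inf
        self.stale = 0
        self.stale_since_decay = 0

    def update(self, val_loss: float) -> Tuple[float, bool, bool]:
        """Feed one epoch's validation loss.

        Returns (current lr, improved, stop_now).
        """
        improved = val_loss < self.best - 0.0
        if improved:
            self.best = val_loss
            self.stale = 0
            self.stale_since_decay = 0
        else:
            self.stale += 1
            self.stale_since_decay += 1
            if self.stale_since_decay >= self.patience:
                self.lr = max(self.lr * self.factor, self.floor)
                self.stale_since_decay = 0
        return self.lr, improved, self.stale >= self.early_stop


def dice_loss(prob: np.ndarray, target: np.ndarray):
    """Soft-Dice loss over the batch; returns (loss, dloss/dprob)."""
    p = prob.ravel()
    g = target.ravel()
    inter = (p * g).sum()
    denom = p.sum() + g.sum() + _EPS
    loss = 1.0 - 2.0 * inter / denom
    dp = (-2.0 * g * denom + 2.0 * inter) / denom ** 2
    return float(loss), dp.reshape(prob.shape)


def bce_loss(prob: np.ndarray, target: np.ndarray):
    """Mean binary cross-entropy; returns (loss, dloss/dprob)."""
    p = np.clip(prob, _EPS, 1.0 - _EPS)
    g = target
    loss = float(-(g * np.log(p) + (1 - g) * np.log(1 - p)).mean())
    dp = (-(g / p) + (1 - g) / (1 - p)) / p.size
    return loss, dp


def _loss_fn(name: str):
    if name == "dice":
        return dice_loss
    if name == "bce":
        return bce_loss

    def combined(prob, target):
        l1, d1 = dice_loss(prob, target)
        l2, d2 = bce_loss(prob, target)
        return l1 + l2, d1 + d2

    return combined


def _snapshot(model: UNet3D) -> list:
    return [
        {k: v.copy() for k, v in l.params.items()} for l in model.layers()
    ]


def _restore(model: UNet3D, snap: list) -> None:
    for l, s in zip(model.layers(), snap):
        for k in l.params:
            l.params[k][...] = s[k]


def _eval_loss(model: UNet3D, data, loss_fn) -> float:
    losses = []
    for x, y in data:
        prob = model.forward(x[None], train=False)
        loss, _ = loss_fn(prob, y[None, None])
        losses.append(loss)
    return float(np.mean(losses))


def train_unet(model: UNet3D, train_set: Sequence, val_set: Sequence,
               cfg: UNetConfig, max_epochs: int = 10_000,
               val_loss_fn: Optional[Callable[[int], float]] = None) -> TrainState:
    """Train to the validation-loss stopping rule.

    ``train_set``/``val_set`` are sequences of (input, mask) pairs where
    input is (2, D, H, W) float (fat and water channels, normalized) and
    mask is (D, H, W) binary.  ``val_loss_fn`` substitutes the validation
    evaluation (used to exercise schedule semantics on stub losses).

    Fully seeded: shuffling derives from cfg.seed; NaN losses abort.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    loss_fn = _loss_fn(cfg.loss_name)
    sched = LRSchedule(cfg.lr_initial, cfg.lr_factor, cfg.lr_patience_epochs,
                       cfg.lr_floor, cfg.early_stop_epochs)
    opt = model.make_optimizer(cfg.lr_initial)
    rng = np.random.default_rng(cfg.seed)
    state = TrainState(lr=cfg.lr_initial)

    for epoch in range(max_epochs):
        state.epoch = epoch
        order = rng.permutation(len(train_set))
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = np.stack([train_set[i][0] for i in idx])
            y = np.stack([train_set[i][1] for i in idx])[:, None]
            prob = model.forward(x, train=True)
            loss, dprob = loss_fn(prob, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {epoch}")
            model.backward(dprob)
            opt.lr = sched.lr
            opt.step()
            train_losses.append(loss)

        if val_loss_fn is not None:
            val_loss = float(val_loss_fn(epoch))
        else:
            val_loss = _eval_loss(model, val_set, loss_fn)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"NaN/inf validation loss at epoch {epoch}")

        lr, improved, stop = sched.update(val_loss)
        state.lr = lr
        if improved:
            state.best_val_loss = val_loss
            state.best_epoch = epoch
            state.epochs_since_improvement = 0
            state.best_params = _snapshot(model)
        else:
            state.epochs_since_improvement += 1
        state.history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(train_losses)),
            "val_loss": val_loss,
            "lr": lr,
        })
        if stop:
            state.stopped_early = True
            break

    if state.best_params is not None:
        _restore(model, state.best_params)
    return state
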