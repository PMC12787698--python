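"""Training recipe: AdamW, cosine-annealed learning rate, 50 epochs.

The loop is fully seeded (weight init happens at build time; shuffling
and dropout are reseeded here) so identical config + seed reproduces
identical loss sequences in single-threaded mode.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .models import EfficientNet, _assign_buffer, save_checkpoint


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    initial_lr: float = 1e-4
    batch_size: int = 32
    dropout: float = 0.2
    weight_decay: float = 1e-2
    min_lr: float = 0.0
    seed: int = 0
    # refresh normalization running statistics from the training set after
    # each epoch; with few optimizer steps the EMA (momentum 0.01) lags far
    # behind the weights and corrupts eval-mode validation
    bn_recalibrate: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not self.initial_lr > self.min_lr >= 0.0:
            raise ValueError("need initial_lr > min_lr >= 0")


@dataclass
class TrainingLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    checkpoint_path: str | None = None

    def write_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss", "lr"])
            for e, (tl, vl, lr) in enumerate(
                    zip(self.train_loss, self.val_loss, self.lr)):
                w.writerow([e, f"{tl:.6f}", f"{vl:.6f}", f"{lr:.10e}"])


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """lr(t) = min_lr + 0.5 (initial_lr - min_lr)(1 + cos(pi t / T))."""
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    span = config.initial_lr - config.min_lr
    return config.min_lr + 0.5 * span * (
        1.0 + math.cos(math.pi * epoch / config.epochs))


def recalibrate_bn(net: EfficientNet, x: np.ndarray, batch_size: int = 32):
    """Set BN running stats to the cumulative average of batch statistics
    computed over ``x`` with frozen weights (deterministic)."""
    bns = [m for m in net.modules() if isinstance(m, nn.BatchNorm2d)]
    if not bns:
        return
    saved_momentum = [b.momentum for b in bns]
    for b in bns:
        b._set_buffer("running_mean", np.zeros_like(b.running_mean))
        b._set_buffer("running_var", np.ones_like(b.running_var))
    for k, i in enumerate(range(0, x.shape[0], batch_size)):
        for b in bns:
            b.momentum = 1.0 / (k + 1)  # cumulative moving average
        net.forward(x[i:i + batch_size], training=True)
    for b, m in zip(bns, saved_momentum):
        b.momentum = m


def _epoch_loss(net: EfficientNet, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> float:
    total, n = 0.0, x.shape[0]
    for i in range(0, n, batch_size):
        logits = net.forward(x[i:i + batch_size])
        loss, _ = nn.cross_entropy(logits, y[i:i + batch_size])
        total += loss * min(batch_size, n - i)
    return total / n


def train(net: EfficientNet, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, config: TrainConfig,
          checkpoint_path: str | Path | None = None) -> TrainingLog:
    """Minimize softmax cross-entropy; keep the best-validation weights."""
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("empty dataset")
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(config.seed)
    net.dropout.p = config.dropout
    net.dropout.rng = np.random.default_rng(rng.integers(2**31))

    opt = nn.AdamW(net.parameters(), lr=config.initial_lr,
                   weight_decay=config.weight_decay)
    log = TrainingLog()
    best_val = math.inf
    best_state = None
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        opt.lr = lr
        order = rng.permutation(n)
        running, seen = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = net.forward(x_train[idx], training=True)
            loss, dlogits = nn.cross_entropy(logits, y_train[idx])
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}")
            net.zero_grad()
            net.backward(dlogits)
            opt.step()
            running += loss * idx.size
            seen += idx.size
        if config.bn_recalibrate:
            recalibrate_bn(net, x_train, config.batch_size)
        val_loss = _epoch_loss(net, x_val, y_val, config.batch_size)
        log.train_loss.append(running / seen)
        log.val_loss.append(val_loss)
        log.lr.append(lr)
        if val_loss < best_val:
            best_val = val_loss
            log.best_epoch = epoch
            best_state = ([p.data.copy() for p in net.parameters()],
                          [(name, b.copy()) for name, b in net.named_buffers()])

    if best_state is not None:
        params, buffers = best_state
        for p, saved in zip(net.parameters(), params):
            p.data = saved
        for name, saved in buffers:
            _assign_buffer(net, name, saved)
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path)
        log.checkpoint_path = str(checkpoint_path)
    return log
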