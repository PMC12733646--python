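"""Training protocol: Nadam, categorical cross-entropy, and four callbacks.

The loop mirrors the common deep-learning callback stack: early stopping on
validation loss (best-weights restoration), reduce-on-plateau halving of the
learning rate, an exponential per-epoch decay that engages after a fixed
epoch, and best-checkpoint tracking. The plateau reduction composes
multiplicatively with the decay schedule: the learning rate at (1-based)
epoch e is

    lr(e) = initial · decay_rate^max(0, e − decay_start_epoch) · 0.5^(plateau events before e)

clipped below at the plateau floor. "Improvement" means a validation-loss
decrease greater than 1e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ._layers import Nadam, softmax_xent
from .model import Model

logger = logging.getLogger(__name__)

MIN_DELTA = 1e-4
LR_FLOOR = 1e-6
PROB_FLOOR = 1e-7


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 32
    shuffle_buffer: int = 1000
    learning_rate: float = 0.001
    max_epochs: int = 50
    early_stop_patience: int = 5
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    decay_start_epoch: int = 10
    decay_rate: float = 0.96
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patiences must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({k: getattr(self, k) for k in
                             ("epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc")})


def cross_entropy_loss(p: np.ndarray, y_onehot: np.ndarray) -> float:
    """L = −Σ_k y_k log p_k (natural log) with a 1e-7 probability floor."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    ax = -1
    losses = -np.sum(y * np.log(np.maximum(p, PROB_FLOOR)), axis=ax)
    return float(np.mean(losses))


def scheduled_lr(epoch: int, current_lr: float, config: TrainingConfig) -> float:
    """Exponential decay step: unchanged through decay_start_epoch, then ×rate."""
    if epoch <= config.decay_start_epoch:
        return current_lr
    return current_lr * config.decay_rate


def _buffered_shuffle(n: int, buffer: int, rng: np.random.Generator) -> np.ndarray:
    """Streaming shuffle through a fixed-size buffer (tf.data semantics)."""
    buf = list(range(min(buffer, n)))
    out = np.empty(n, dtype=np.int64)
    nxt = len(buf)
    for i in range(n):
        j = rng.integers(0, len(buf))
        out[i] = buf[j]
        if nxt < n:
            buf[j] = nxt
            nxt += 1
        else:
            buf[j] = buf[-1]
            buf.pop()
    return out


def _evaluate(model: Model, images: np.ndarray, y_onehot: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    n = len(images)
    for i in range(0, n, batch_size):
        xb, yb = images[i:i + batch_size], y_onehot[i:i + batch_size]
        logits, probs, _ = model.forward_batch(xb)
        losses.append(cross_entropy_loss(probs, yb) * len(xb))
        correct += int((probs.argmax(1) == yb.argmax(1)).sum())
    return sum(losses) / n, correct / n


def train(model: Model, train_set, val_set, config: TrainingConfig | None = None
          ) -> TrainingHistory:
    """Fit the model; on return it carries the best-validation-loss weights.

    train_set / val_set are (images, labels) pairs; labels are integer class
    indices. Raises on empty datasets and aborts on non-finite loss.
    """
    config = config or TrainingConfig()
    x_tr, y_tr = np.asarray(train_set[0]), np.asarray(train_set[1])
    x_va, y_va = np.asarray(val_set[0]), np.asarray(val_set[1])
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be nonempty")
    k = model.config.n_classes
    yt = np.eye(k, dtype=np.float32)[y_tr]
    yv = np.eye(k, dtype=np.float32)[y_va]

    rng = np.random.default_rng(config.seed)
    opt = Nadam(model.params, lr=config.learning_rate)
    hist = TrainingHistory()
    monitor_loss = np.inf   # early-stop / plateau monitor (min-delta 1e-4)
    ckpt_loss = np.inf      # checkpoint monitor (any strict improvement)
    best_weights = model.copy_weights()
    best_epoch = 0
    es_wait = 0
    plateau_wait = 0
    plateau_events = 0

    for epoch in range(1, config.max_epochs + 1):
        decay = config.decay_rate ** max(0, epoch - config.decay_start_epoch)
        # the floor never raises the lr above its configured initial value
        floor = min(LR_FLOOR, config.learning_rate)
        lr = max(config.learning_rate * decay
                 * config.plateau_factor ** plateau_events, floor)
        opt.lr = lr

        order = _buffered_shuffle(len(x_tr), config.shuffle_buffer, rng)
        ep_loss, ep_correct = 0.0, 0
        for bi, i in enumerate(range(0, len(order), config.batch_size)):
            sel = order[i:i + config.batch_size]
            xb, yb = x_tr[sel], yt[sel]
            logits, _, cc = model.forward_batch(xb, cache=True)
            loss, dlogits, probs = softmax_xent(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}")
            grads, _ = model.backward(cc, dlogits)
            opt.step(grads)
            ep_loss += loss * len(xb)
            ep_correct += int((probs.argmax(1) == yb.argmax(1)).sum())
        train_loss = ep_loss / len(x_tr)
        train_acc = ep_correct / len(x_tr)
        val_loss, val_acc = _evaluate(model, x_va, yv, config.batch_size)

        hist.epoch.append(epoch)
        hist.lr.append(lr)
        hist.train_loss.append(train_loss)
        hist.train_acc.append(train_acc)
        hist.val_loss.append(val_loss)
        hist.val_acc.append(val_acc)
        logger.info("epoch %d lr=%.2e train_loss=%.4f train_acc=%.4f "
                    "val_loss=%.4f val_acc=%.4f",
                    epoch, lr, train_loss, train_acc, val_loss, val_acc)

        if val_loss < ckpt_loss:
            ckpt_loss = val_loss
            best_weights = model.copy_weights()
            best_epoch = epoch
        if val_loss < monitor_loss - MIN_DELTA:
            monitor_loss = val_loss
            es_wait = 0
            plateau_wait = 0
        else:
            es_wait += 1
            plateau_wait += 1
            if plateau_wait >= config.plateau_patience:
                plateau_events += 1
                plateau_wait = 0
                logger.info("plateau: halving learning rate (event %d)", plateau_events)
            if es_wait >= config.early_stop_patience:
                logger.info("early stopping at epoch %d", epoch)
                break

    hist.stopped_epoch = epoch
    hist.best_epoch = best_epoch if best_epoch else int(np.argmin(hist.val_loss)) + 1
    model.set_weights(best_weights)
    return hist
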