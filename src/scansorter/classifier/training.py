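"""Training protocol for the slice CNN.

Cross-entropy loss, Glorot-uniform initialization, Adam (lr 0.001,
beta1 0.9, beta2 0.999), batch size 32, at most 100 epochs; the learning
rate drops by a factor 10 (floor 1e-7) after 3 epochs without a training
loss below the running best, and training stops after 6 such epochs.
Both schedule decisions are pure functions of the recorded loss history,
so a run can be replayed and audited from its history file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..labels import CLASS_LABELS
from .layers import cross_entropy, softmax
from .model import SliceCNN


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 100
    plateau_patience: int = 3
    lr_factor: float = 10.0
    min_lr: float = 1e-7
    stop_patience: int = 6
    seed: int = 0
    loss: str = "cross_entropy"
    init: str = "glorot_uniform"

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "max_epochs", "plateau_patience",
                     "lr_factor", "min_lr", "stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_lr >= self.learning_rate:
            raise ValueError("min_lr must be below the initial learning rate")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def lr_schedule_step(loss_history: Sequence[float], current_lr: float,
                     cfg: TrainConfig) -> float:
    """Plateau schedule: divide the learning rate by ``lr_factor`` when the
    last ``plateau_patience`` epochs never went strictly below the best loss
    seen before them; never below ``min_lr``."""
    if not len(loss_history):
        raise ValueError("loss history must be non-empty")
    p = cfg.plateau_patience
    if len(loss_history) <= p:
        return current_lr
    best_before = min(loss_history[:-p])
    if min(loss_history[-p:]) < best_before:
        return current_lr
    return max(current_lr / cfg.lr_factor, cfg.min_lr)


def should_stop(loss_history: Sequence[float], epoch: int, cfg: TrainConfig) -> bool:
    """True at the epoch cap, or when the last ``stop_patience`` epochs never
    improved on the best loss before them."""
    if epoch < 1:
        raise ValueError("epoch must be >= 1")
    if epoch >= cfg.max_epochs:
        return True
    s = cfg.stop_patience
    if len(loss_history) <= s:
        return False
    return min(loss_history[-s:]) >= min(loss_history[:-s])


class _Adam:
    def __init__(self, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, items, lr: float) -> None:
        cfg = self.cfg
        self.t += 1
        b1, b2 = cfg.beta1, cfg.beta2
        for key, layer, name in items:
            g = layer.grads[name]
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            layer.params[name] -= lr * mhat / (np.sqrt(vhat) + cfg.epsilon)


def train(model: SliceCNN, pixels: np.ndarray, four_d: np.ndarray,
          labels: np.ndarray, cfg: Optional[TrainConfig] = None,
          pre_pooled: bool = False) -> pd.DataFrame:
    """Train in place; returns the per-epoch history (epoch, loss, lr, accuracy).

    ``pixels`` is ``(N, 1, H, W)``; slices are treated as independent
    samples.  Every class must be represented.  With ``pre_pooled`` the
    inputs are already at the model's working resolution (the caller used
    :meth:`SliceCNN.pool_input`), which avoids re-pooling each epoch.
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    four_d = np.asarray(four_d, dtype=np.float32)
    present = set(np.unique(labels).tolist())
    missing = [CLASS_LABELS[i] for i in range(len(CLASS_LABELS)) if i not in present]
    if missing:
        raise ValueError(f"training data lacks samples for classes: {missing}")

    x = np.asarray(pixels, dtype=np.float32)
    if not pre_pooled:
        x = model.pool_input(x)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    adam = _Adam(cfg)
    n = x.shape[0]
    lr = cfg.learning_rate
    items = model.parameter_items()

    records = []
    losses: list[float] = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, fb, yb = x[idx], four_d[idx], labels[idx]
            logits = model.forward_pooled(xb, fb, training=True)
            probs = softmax(logits)
            total_loss += cross_entropy(probs, yb) * len(idx)
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = (probs - np.eye(probs.shape[1], dtype=np.float32)[yb]) / len(idx)
            model.backward_pooled(grad.astype(np.float32))
            adam.step(items, lr)
        epoch_loss = total_loss / n
        losses.append(epoch_loss)
        records.append({"epoch": epoch, "loss": epoch_loss, "lr": lr,
                        "accuracy": correct / n})
        if should_stop(losses, epoch, cfg):
            break
        lr = lr_schedule_step(losses, lr, cfg)
    return pd.DataFrame.from_records(records)


def save_history(history: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    history.to_csv(path, sep="\t", index=False)
    return path
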