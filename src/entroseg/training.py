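"""Training harness: softmax Dice loss, Adam, plateau learning-rate halving.

The loss is the soft Dice of the softmax foreground channel,
``1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)`` with smoothing
``eps = 1`` so empty targets are handled gracefully.  The schedule follows
the training protocol: Adam at ``lr0``, halved whenever the validation Dice
has not improved for ``plateau_patience`` epochs.  Validation Dice is the
hard Dice of patch predictions thresholded at 0.5 — a tractable per-epoch
signal; the full recombination pipeline is evaluated separately.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .model import AneurysmSegNet, ModelConfig
from .selection import PatchTriplet

EPS = 1.0  # Dice smoothing
IMPROVE_TOL = 1e-6  # minimum validation-Dice gain that counts as improvement


@dataclasses.dataclass
class TrainConfig:
    lr0: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    plateau_patience: int = 15
    lr_factor: float = 0.5
    seed: int = 0
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)  # train/val/test fractions
    max_steps: int | None = None  # optional hard cap on optimiser steps

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def dice_loss(prob, target, eps: float = EPS):
    """Soft Dice loss in [0, 1]; differentiable when given autodiff tensors.

    `prob` is the foreground probability map, `target` the binary mask.
    Returns a Tensor when `prob` is a Tensor, otherwise a float.
    """
    is_tensor = isinstance(prob, nn.Tensor)
    p = prob if is_tensor else nn.Tensor(np.asarray(prob, dtype=np.float64))
    g = np.asarray(target.data if isinstance(target, nn.Tensor) else target, dtype=p.data.dtype)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prob {p.shape} vs target {g.shape}")
    inter = (p * nn.Tensor(g)).sum()
    denom = p.sum() + float(g.sum()) + eps
    loss = 1.0 - (2.0 * inter + eps) / denom
    return loss if is_tensor else float(loss.data)


def hard_dice(prob: np.ndarray, target: np.ndarray, threshold: float = 0.5) -> float:
    """Dice of the thresholded prediction (both-empty convention: 1)."""
    pred = np.asarray(prob) >= threshold
    target = np.asarray(target).astype(bool)
    s = pred.sum() + target.sum()
    if s == 0:
        return 1.0
    return float(2.0 * (pred & target).sum() / s)


def split_samples(
    n_samples: int, split: tuple[float, float, float], seed: int
) -> tuple[list[int], list[int], list[int]]:
    """Random sample-level (volume-level) split; every index lands in one part."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    n_train = int(round(split[0] * n_samples))
    n_val = int(round(split[1] * n_samples))
    n_train = min(n_train, n_samples)
    n_val = min(n_val, n_samples - n_train)
    return (
        sorted(order[:n_train].tolist()),
        sorted(order[n_train : n_train + n_val].tolist()),
        sorted(order[n_train + n_val :].tolist()),
    )


class PlateauScheduler:
    """Halve the learning rate when the monitored score stalls for `patience` epochs."""

    def __init__(self, optimizer: nn.Adam, patience: int, factor: float = 0.5):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.best = -np.inf
        self.stale = 0

    def step(self, score: float) -> bool:
        """Report a new validation score; returns True if the lr was reduced."""
        if score > self.best + IMPROVE_TOL:
            self.best = score
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.optimizer.lr *= self.factor
            self.stale = 0
            return True
        return False


def _as_arrays(triplets: list[PatchTriplet]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([t.channels for t in triplets]).astype(np.float32)
    y = np.stack([t.target for t in triplets]).astype(np.float32)
    return x, y


def _batch_loss(model: AneurysmSegNet, x: np.ndarray, y: np.ndarray) -> nn.Tensor:
    probs = model.forward(x)  # B, 2, H, W
    fg = _select_channel(probs, 1)
    return dice_loss(fg, y)


def _select_channel(t: nn.Tensor, ch: int) -> nn.Tensor:
    out_data = t.data[:, ch]

    def bwd(g):
        full = np.zeros_like(t.data)
        full[:, ch] = g
        t._accumulate(full)

    return nn.Tensor(out_data, parents=(t,), backward=bwd)


def evaluate_patch_dice(model: AneurysmSegNet, triplets: list[PatchTriplet],
                        batch_size: int = 8) -> float:
    """Mean hard Dice of per-patch predictions at threshold 0.5."""
    x, y = _as_arrays(triplets)
    scores = []
    for i in range(0, len(x), batch_size):
        probs = model.predict_proba(x[i : i + batch_size])
        scores.extend(hard_dice(p, t) for p, t in zip(probs, y[i : i + batch_size]))
    return float(np.mean(scores))


def train(
    train_triplets: list[PatchTriplet],
    val_triplets: list[PatchTriplet],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    model: AneurysmSegNet | None = None,
    log_path=None,
) -> tuple[AneurysmSegNet, list[dict]]:
    """Train the segmentation network; returns the model and per-epoch history.

    Fully seeded: model initialisation comes from ``model_config.seed``,
    batch shuffling and dropout from ``train_config.seed``.  Raises on empty
    splits and aborts with diagnostics on a non-finite loss.
    """
    train_config = train_config or TrainConfig()
    if not train_triplets or not val_triplets:
        raise ValueError("train and validation splits must be non-empty")
    model = model or AneurysmSegNet(model_config or ModelConfig())
    rng = np.random.default_rng(train_config.seed)
    model._drop_rng = rng  # dropout noise follows the training seed
    opt = nn.Adam(model.parameters(), lr=train_config.lr0)
    sched = PlateauScheduler(opt, train_config.plateau_patience, train_config.lr_factor)

    x_train, y_train = _as_arrays(train_triplets)
    history: list[dict] = []
    log_fh = open(log_path, "a") if log_path else None
    steps = 0
    try:
        for epoch in range(train_config.epochs):
            model.train()
            order = rng.permutation(len(x_train))
            losses = []
            for i in range(0, len(order), train_config.batch_size):
                idx = order[i : i + train_config.batch_size]
                loss = _batch_loss(model, x_train[idx], y_train[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} step {steps}: {loss.data!r}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                steps += 1
                if train_config.max_steps and steps >= train_config.max_steps:
                    break
            val_dice = evaluate_patch_dice(model, val_triplets)
            reduced = sched.step(val_dice)
            record = {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)) if losses else float("nan"),
                "val_dice": val_dice,
                "lr": opt.lr,
                "lr_reduced": reduced,
                "steps": steps,
            }
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if train_config.max_steps and steps >= train_config.max_steps:
                break
    finally:
        if log_fh:
            log_fh.close()
    return model, history


def history_to_csv(history: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(Path(path), index=False)
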