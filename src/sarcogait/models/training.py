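"""Mini-batch training loop and optimizers for the functional models.

Optimizers operate on the flattened parameter vector.  ``sgd`` supports
momentum, L2 weight decay and a cosine-annealing learning-rate schedule;
``adam`` uses the standard bias-corrected moments.  The loop keeps the
parameters with the best validation accuracy seen at any epoch end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from . import layers as L

__all__ = ["TrainHistory", "train_classifier", "predict_proba", "accuracy"]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0


def _cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    return 0.5 * lr0 * (1.0 + np.cos(np.pi * epoch / max(total_epochs, 1)))


def predict_proba(model, x: np.ndarray, params=None, batch_size: int = 64) -> np.ndarray:
    """Eval-mode probabilities, computed in batches to bound memory."""
    outs = [model.forward(x[i:i + batch_size], params=params)
            for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def accuracy(model, x: np.ndarray, y: np.ndarray, params=None) -> float:
    if len(x) == 0:
        raise ValueError("cannot score an empty set")
    pred = predict_proba(model, x, params=params).argmax(axis=1)
    return float(np.mean(pred == y))


def train_classifier(
    model,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    *,
    epochs: int = 10,
    lr: float = 0.001,
    optimizer: str = "adam",
    momentum: float = 0.9,
    weight_decay: float = 0.0,
    schedule: str = "none",
    batch_size: int = 16,
    seed: int = 0,
    max_steps: int | None = None,
    augment_fn=None,
) -> TrainHistory:
    """Train ``model`` in place with cross-entropy loss.

    If a validation set is given, the parameters achieving the best
    validation accuracy (earliest epoch on ties) are restored at the end;
    otherwise the final parameters are kept.
    """
    if optimizer not in ("adam", "sgd"):
        raise ValueError(f"unknown optimizer {optimizer!r}")
    if schedule not in ("none", "cosine_annealing"):
        raise ValueError(f"unknown schedule {schedule!r}")
    y_train = np.asarray(y_train, dtype=int)
    rng = np.random.default_rng(seed)
    flat, unflatten = flatten(model.params)
    flat = flat.astype(float)

    def loss_flat(p_flat, xb, yb):
        return L.cross_entropy(model.logits(unflatten(p_flat), xb, train=True), yb)

    grad_fn = value_and_grad(loss_flat)

    vel = np.zeros_like(flat)
    m1 = np.zeros_like(flat)
    m2 = np.zeros_like(flat)
    adam_t = 0
    history = TrainHistory()
    best_flat = flat.copy()
    steps_done = 0
    n = len(x_train)

    for epoch in range(epochs):
        lr_t = _cosine_lr(lr, epoch, epochs) if schedule == "cosine_annealing" else lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = x_train[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            value, g = grad_fn(flat, xb, y_train[idx])
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {steps_done}")
            losses.append(float(value))
            if weight_decay:
                g = g + weight_decay * flat
            if optimizer == "sgd":
                vel = momentum * vel - lr_t * g
                flat = flat + vel
            else:
                adam_t += 1
                m1 = 0.9 * m1 + 0.1 * g
                m2 = 0.999 * m2 + 0.001 * g * g
                mhat = m1 / (1 - 0.9 ** adam_t)
                vhat = m2 / (1 - 0.999 ** adam_t)
                flat = flat - lr_t * mhat / (np.sqrt(vhat) + 1e-8)
            steps_done += 1
            if max_steps is not None and steps_done >= max_steps:
                break
        history.train_loss.append(float(np.mean(losses)))
        if x_val is not None and len(x_val):
            val_acc = accuracy(model, x_val, y_val, params=unflatten(flat))
            history.val_accuracy.append(val_acc)
            # ">=": among tying epochs keep the latest (most trained) — with
            # small validation sets early epochs often tie at the ceiling
            if val_acc >= history.best_val_accuracy:
                history.best_val_accuracy = val_acc
                history.best_epoch = epoch
                best_flat = flat.copy()
        else:
            best_flat = flat
        if max_steps is not None and steps_done >= max_steps:
            break

    model.params = unflatten(best_flat if x_val is not None else flat)
    return history
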