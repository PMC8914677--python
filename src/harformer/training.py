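"""Training recipe: warmup + cosine schedule, label-smoothed per-timestep
cross-entropy, Adam with global gradient-norm clipping, and tracking of the
best validation accuracy over epochs.

Defaults mirror the optimized full-scale recipe: 50 epochs, batch size 64,
peak learning rate 1e-3 reached after 10 warmup update steps and decayed to
zero along a half cosine over the remaining steps, global clipnorm 3.0,
label smoothing 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    HARTransformerParams,
    backward,
    forward,
    forward_with_cache,
)

__all__ = [
    "TrainConfig",
    "TrainState",
    "TrainingDivergedError",
    "lr_at_step",
    "smoothed_cross_entropy",
    "per_timestep_accuracy",
    "clip_global_norm",
    "train",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    max_lr: float = 1e-3
    warmup_steps: int = 10
    global_clipnorm: float = 3.0
    label_smoothing: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size positive")
        if self.max_lr <= 0 or self.warmup_steps < 0:
            raise ValueError("max_lr must be positive, warmup_steps >= 0")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.global_clipnorm <= 0:
            raise ValueError("global_clipnorm must be positive")


@dataclass
class TrainState:
    """Step/epoch counters, per-epoch history, and the best validation
    accuracy seen so far (non-decreasing by construction)."""

    step: int = 0
    epoch: int = 0
    best_validation_accuracy: float = 0.0
    best_epoch: int = -1
    history: list[dict] = field(default_factory=list)


def lr_at_step(step: int, config: TrainConfig, total_steps: int) -> float:
    """Linear ramp 0 -> max_lr over ``warmup_steps`` updates, then cosine
    decay ``max_lr * 0.5 * (1 + cos(pi (s-w)/(total-w)))`` to zero."""
    if step < 0 or step > total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    w = config.warmup_steps
    if w >= total_steps:
        raise ValueError("warmup_steps must be smaller than total_steps")
    if step <= w:
        return config.max_lr * (step / w if w > 0 else 1.0)
    progress = (step - w) / (total_steps - w)
    return config.max_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def smoothed_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    smoothing: float = 0.1,
    return_grad: bool = False,
):
    """Label-smoothed cross-entropy, averaged over all timesteps.

    Targets mix the one-hot label with the uniform distribution:
    ``(1 - eps) * onehot + eps / K`` (the true class keeps
    ``1 - eps + eps/K``). Accepts ``(T, K)`` or batched ``(B, T, K)``
    logits with matching integer labels.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    k = logits.shape[-1]
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
        raise ValueError(f"labels outside 0..{k - 1}")
    logp = _log_softmax(logits)
    n = labels.size
    true_logp = np.take_along_axis(logp, labels[..., None], axis=-1)[..., 0]
    loss = -(
        (1.0 - smoothing) * true_logp.sum() + smoothing / k * logp.sum()
    ) / n
    if not return_grad:
        return float(loss)
    target = np.full_like(logp, smoothing / k)
    np.put_along_axis(
        target, labels[..., None],
        smoothing / k + (1.0 - smoothing), axis=-1,
    )
    dlogits = (np.exp(logp) - target) / n
    return float(loss), dlogits


def per_timestep_accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of timesteps whose argmax logit matches the label (argmax
    ties resolve to the lowest class index)."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = logits.argmax(axis=-1)
    return float((pred == labels).mean())


def clip_global_norm(
    grads: dict[str, np.ndarray], clipnorm: float
) -> tuple[dict[str, np.ndarray], float]:
    """Scale all gradients jointly so the global L2 norm is <= clipnorm.

    Returns the (possibly scaled) gradients and the post-clip global norm.
    """
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > clipnorm:
        factor = clipnorm / total
        grads = {k: g * factor for k, g in grads.items()}
        return grads, clipnorm
    return grads, total


class AdamOptimizer:
    """Standard Adam with bias correction; learning rate passed per step."""

    def __init__(self, config: TrainConfig):
        self.cfg = config
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(
        self,
        params: HARTransformerParams,
        grads: dict[str, np.ndarray],
        lr: float,
    ) -> None:
        b1, b2, eps = self.cfg.adam_beta1, self.cfg.adam_beta2, self.cfg.adam_epsilon
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, tensor in params.named_tensors():
            g = grads[name]
            m = self.m.setdefault(name, np.zeros_like(tensor))
            v = self.v.setdefault(name, np.zeros_like(tensor))
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            tensor -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _evaluate_accuracy(
    params: HARTransformerParams, x: np.ndarray, y: np.ndarray, batch_size: int
) -> float:
    correct = 0
    for start in range(0, len(x), batch_size):
        logits = forward(x[start : start + batch_size], params, training=False)
        correct += int((logits.argmax(axis=-1) == y[start : start + batch_size]).sum())
    return correct / y.size if y.size else 0.0


def train(
    params: HARTransformerParams,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> tuple[HARTransformerParams, TrainState]:
    """Run the full recipe and return the best-validation parameters.

    ``train_data``/``val_data`` are ``(X, Y)`` pairs with ``X`` of shape
    (n, T, C) and per-timestep integer labels ``Y`` of shape (n, T). The
    normalizer inside ``params`` is used as-is (fit it beforehand with
    :func:`harformer.model.fit_normalizer`). Each update clips the global
    gradient norm before the Adam step; validation accuracy is measured
    every epoch and the parameters achieving the best value are returned
    (a copy; with ``epochs=0`` the initial parameters come back unchanged).
    """
    x_train, y_train = (np.asarray(a) for a in train_data)
    x_val, y_val = (np.asarray(a) for a in val_data)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")

    state = TrainState()
    best = params.copy()
    if config.epochs == 0:
        return best, state

    rng = np.random.default_rng(config.seed)
    n = len(x_train)
    steps_per_epoch = math.ceil(n / config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    # very short runs: shrink warmup so the cosine phase exists at all
    if config.warmup_steps >= total_steps:
        from dataclasses import replace

        config = replace(config, warmup_steps=max(total_steps - 1, 0))
    optimizer = AdamOptimizer(config)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        max_clipped_norm = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            logits, cache, _ = forward_with_cache(xb, params, training=True, rng=rng)
            loss, dlogits = smoothed_cross_entropy(
                logits, yb, config.label_smoothing, return_grad=True
            )
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {epoch}, step {state.step}"
                )
            grads = backward(dlogits, params, cache)
            grads, norm = clip_global_norm(grads, config.global_clipnorm)
            max_clipped_norm = max(max_clipped_norm, norm)
            lr = lr_at_step(state.step + 1, config, total_steps)
            optimizer.step(params, grads, lr)
            state.step += 1
            epoch_loss += loss * len(batch)
            epoch_correct += int((logits.argmax(axis=-1) == yb).sum())

        val_acc = _evaluate_accuracy(params, x_val, y_val, config.batch_size)
        state.epoch = epoch + 1
        record = {
            "epoch": epoch + 1,
            "train_loss": epoch_loss / n,
            "train_accuracy": epoch_correct / y_train.size,
            "val_accuracy": val_acc,
            "lr": lr_at_step(state.step, config, total_steps),
            "max_clipped_grad_norm": max_clipped_norm,
        }
        state.history.append(record)
        if val_acc > state.best_validation_accuracy or state.best_epoch < 0:
            state.best_validation_accuracy = val_acc
            state.best_epoch = epoch + 1
            best = params.copy()

    return best, state
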