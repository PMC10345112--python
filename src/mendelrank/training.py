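"""Class-weighted SGD training with the one-cycle learning-rate policy.

The schedule ramps the learning rate linearly from 0.001 to 0.1 over the
first 30% of training steps while momentum anneals 0.95 -> 0.85, then decays
the learning rate linearly to 4e-7 while momentum returns to 0.95.  Setting
``literal_text_mode`` reproduces the variant in which phase-2 momentum
restarts from 0.95 and anneals down to 0.85 again.

Class weights rescale each example's cross-entropy contribution: with
weights (1, 2, 7) a recessive variant contributes seven times as much loss
as a benign one, pushing the minority pathogenic classes' recall up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import EncodedBatch, MemberSpec, Module, build_model
from .nn.autodiff import Tensor


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    epochs: int = 20
    max_lr: float = 0.1
    init_lr: float = 0.001
    final_lr: float = 4e-7
    init_momentum: float = 0.95
    min_momentum: float = 0.85
    warm_fraction: float = 0.3
    seed: int = 0
    literal_text_mode: bool = False

    def __post_init__(self):
        if not 0 < self.warm_fraction < 1:
            raise ValueError("warm_fraction must be in (0, 1)")
        if not self.init_lr < self.max_lr:
            raise ValueError("init_lr must be below max_lr")
        if not self.final_lr < self.init_lr:
            raise ValueError("final_lr must be below init_lr")


def onecycle(step: int, total_steps: int, cfg: TrainConfig) -> tuple[float, float]:
    """Learning rate and momentum at ``step`` of ``total_steps``.

    Piecewise-linear and continuous; the peak learning rate is attained
    exactly once, at the end of the warm-up phase.
    """
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    boundary = cfg.warm_fraction * total_steps
    if step <= boundary:
        f = step / boundary if boundary > 0 else 1.0
        lr = cfg.init_lr + f * (cfg.max_lr - cfg.init_lr)
        mom = cfg.init_momentum + f * (cfg.min_momentum - cfg.init_momentum)
    else:
        f = (step - boundary) / (total_steps - boundary)
        lr = cfg.max_lr + f * (cfg.final_lr - cfg.max_lr)
        if cfg.literal_text_mode:
            mom = cfg.init_momentum + f * (cfg.min_momentum - cfg.init_momentum)
        else:
            mom = cfg.min_momentum + f * (cfg.init_momentum - cfg.min_momentum)
    return lr, mom


def weighted_loss(probs: Sequence[float], label: int,
                  weights: Sequence[float], eps: float = 1e-12) -> float:
    """Class-weighted categorical cross-entropy of one prediction."""
    if min(weights) <= 0:
        raise ValueError("class weights must be positive")
    p = float(probs[label])
    return -weights[label] * float(np.log(max(p, eps)))


def weighted_loss_batch(logits: Tensor, labels: np.ndarray,
                        weights: Sequence[float]) -> Tensor:
    """Mean class-weighted cross-entropy over a batch, from logits."""
    if min(weights) <= 0:
        raise ValueError("class weights must be positive")
    ls = logits.log_softmax(axis=-1)
    idx = (np.arange(labels.shape[0]), labels)
    w = np.asarray(weights, dtype=float)[labels]
    return (ls[idx] * -w).mean()


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Plain (unweighted) categorical cross-entropy of probabilities."""
    p = np.clip(probs[np.arange(labels.shape[0]), labels], eps, 1.0)
    return float(-np.log(p).mean())


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)       # per epoch
    val_cross_entropy: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)          # per step
    best_epoch: int = -1


class SGDMomentum:
    """Classic momentum SGD: v <- m*v - lr*g; w <- w + v."""

    def __init__(self, params: Sequence[Tensor]):
        self.params = list(params)
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float, momentum: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= momentum
            v -= lr * p.grad
            p.data += v
            p.grad = None


def train_member(train_batch: EncodedBatch, train_labels: np.ndarray,
                 cfg: TrainConfig, spec: MemberSpec, model_cfg,
                 val_batch: Optional[EncodedBatch] = None,
                 val_labels: Optional[np.ndarray] = None,
                 ) -> tuple[Module, TrainHistory]:
    """Train one ensemble member; returns the best-validation-epoch model.

    Fully deterministic given (seed, config, data): parameter initialization
    and batch shuffling both derive from ``cfg.seed``.  Divergence (NaN loss)
    aborts with a diagnostic.
    """
    n = train_batch.size
    if n == 0:
        raise ValueError("training data is empty")
    model = build_model(spec.architecture, model_cfg, seed=cfg.seed)
    params = model.parameters()
    opt = SGDMomentum(params)
    rng = np.random.default_rng(cfg.seed + 1)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs
    history = TrainHistory()
    best_val = np.inf
    best_params = [p.data.copy() for p in params]
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            lr, mom = onecycle(step, total_steps, cfg)
            history.lr_trace.append(lr)
            logits = model.logits(train_batch.subset(idx))
            loss = weighted_loss_batch(logits, train_labels[idx],
                                       spec.class_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (loss={loss.data}) at epoch {epoch}, "
                    f"step {step}, lr={lr:.3g}")
            loss.backward()
            opt.step(lr, mom)
            epoch_losses.append(float(loss.data))
            step += 1
        history.train_loss.append(float(np.mean(epoch_losses)))
        if val_batch is not None and val_labels is not None:
            val_probs = model.forward(val_batch).data
            ce = cross_entropy(val_probs, val_labels)
        else:
            ce = history.train_loss[-1]
        history.val_cross_entropy.append(ce)
        if ce < best_val:
            best_val = ce
            best_epoch = epoch
            best_params = [p.data.copy() for p in params]
            history.best_epoch = best_epoch
    for p, best in zip(params, best_params):
        p.data[...] = best
    return model, history
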