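"""Training with focal loss, AdamW, and a warmup + cosine schedule.

The loss is evaluated over all 800 positions and 3 classes (neither /
acceptor / donor), summed over classes and positions and averaged over the
batch; probabilities are clipped at 1e-10 before the log.  Focal loss
down-weights easy positions by (1 - P)^gamma, which matters here because
798 of 800 positions of every example are the neither class.  At evaluation
time only the donor score (position 200) and acceptor score (position 600)
are read out, and a junction is called positive when
min(donor, acceptor) >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import encode as enc
from .model import SpliceSiteNet, Parameter

__all__ = [
    "TrainConfig",
    "cross_entropy",
    "focal_loss",
    "focal_loss_grad",
    "lr_at_step",
    "AdamW",
    "train",
    "score_examples",
    "evaluate",
]

_EPS = 1e-10


@dataclass
class TrainConfig:
    batch_size: int = 100
    epochs: int = 15
    peak_lr: float = 0.03
    warmup_steps: int = 1000
    gamma: float = 2.0
    weight_decay: float = 0.01
    grad_clip: float = 10.0  # global gradient-norm ceiling; None disables
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")


def _batched(labels, probs):
    labels = np.asarray(labels, dtype=np.float64)
    probs = np.asarray(probs, dtype=np.float64)
    if labels.ndim == 2:
        labels, probs = labels[None], probs[None]
    return labels, np.clip(probs, _EPS, 1.0)


def cross_entropy(labels, probs) -> float:
    """Mean over batch of -sum(I * log P) over classes and positions."""
    labels, probs = _batched(labels, probs)
    return float(-(labels * np.log(probs)).sum() / labels.shape[0])


def focal_loss(labels, probs, gamma: float = 2.0) -> float:
    """Mean over batch of -sum(I * (1-P)^gamma * log P); gamma=0 recovers
    plain cross-entropy."""
    labels, probs = _batched(labels, probs)
    return float(-(labels * (1.0 - probs) ** gamma * np.log(probs)).sum() / labels.shape[0])


def focal_loss_grad(labels, probs, gamma: float = 2.0):
    """(loss, d loss / d probs) for a batch, matching :func:`focal_loss`."""
    squeeze = np.asarray(labels).ndim == 2
    labels, probs = _batched(labels, probs)
    b = labels.shape[0]
    one_m = 1.0 - probs
    logp = np.log(probs)
    loss = float(-(labels * one_m**gamma * logp).sum() / b)
    if gamma == 0:
        grad = -labels / probs / b
    else:
        grad = labels * (gamma * one_m ** (gamma - 1.0) * logp - one_m**gamma / probs) / b
    grad = grad.astype(np.float32)
    return loss, grad[0] if squeeze else grad


def focal_loss_logit_grad(labels, probs, gamma: float = 2.0):
    """(loss, d loss / d logits) with the softmax Jacobian folded in.

    Because every position's label is one-hot (the neither class included),
    the fused gradient has the closed form h * (Y - P), where h depends only
    on the true-class probability:

        h = gamma * (1 - Pc)^(gamma-1) * Pc * log(Pc) - (1 - Pc)^gamma

    (h = -1 for gamma = 0, recovering the familiar P - Y).  Unlike the
    probability-space gradient, this form is bounded even when the predicted
    probability of the true class underflows, which keeps AdamW's second
    moments sane under the extreme 798:2 class imbalance per example.
    """
    labels, probs = _batched(labels, probs)
    b = labels.shape[0]
    pc = (labels * probs).sum(axis=1, keepdims=True)  # true-class probability
    one_m = 1.0 - pc
    logpc = np.log(pc)
    loss = float(-(one_m**gamma * logpc).sum() / b)
    if gamma == 0:
        h = -np.ones_like(pc)
    else:
        h = gamma * one_m ** (gamma - 1.0) * pc * logpc - one_m**gamma
    grad = h * (labels - probs) / b
    return loss, grad.astype(np.float32)


def lr_at_step(step: int, total_steps: int, config: TrainConfig) -> float:
    """Linear ramp 0 -> peak over the warmup, then cosine decay peak -> 0."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    warmup = min(config.warmup_steps, total_steps)
    if step < warmup:
        return config.peak_lr * step / warmup
    if total_steps == warmup:
        return config.peak_lr
    frac = (step - warmup) / (total_steps - warmup)
    return config.peak_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


def clip_grad_norm(params, max_norm: float) -> float:
    """Rescale all gradients so their global L2 norm is at most ``max_norm``.

    Occasional mini-batches produce gradient spikes orders of magnitude above
    typical; unclipped, these inflate Adam's second moments and stall the
    remainder of a short training run.  Returns the pre-clip norm.
    """
    total = float(np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum()) for p in params)))
    if total > max_norm and total > 0:
        scale = np.float32(max_norm / total)
        for p in params:
            p.grad *= scale
    return total


class AdamW:
    """AdamW with decoupled weight decay (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: list[Parameter], weight_decay: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= np.float32(lr) * (update + self.weight_decay * p.data)


def train(model: SpliceSiteNet, X: np.ndarray, Y: np.ndarray,
          config: TrainConfig | None = None, log=None):
    """Train in place; returns (per-epoch mean losses, per-step log rows).

    ``X`` is (N, 4, 800) one-hot inputs, ``Y`` (N, 3, 800) labels.  Example
    order is shuffled each epoch with a generator seeded from the config, so
    identical configs give identical loss histories.
    """
    config = config or TrainConfig()
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), weight_decay=config.weight_decay)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    history, rows = [], []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            lr = lr_at_step(step, total_steps, config)
            probs = model.forward(X[idx], training=True)
            loss, grad = focal_loss_logit_grad(Y[idx], probs, config.gamma)
            model.zero_grad()
            model.backward_logits(grad)
            if config.grad_clip is not None:
                clip_grad_norm(model.parameters(), config.grad_clip)
            opt.step(lr)
            losses.append(loss)
            rows.append({"epoch": epoch, "step": step, "lr": lr, "loss": loss})
            if log is not None:
                log.write(f"{epoch}\t{step}\t{lr:.6g}\t{loss:.6g}\n")
            step += 1
        history.append(float(np.mean(losses)))
    return history, rows


def score_examples(model: SpliceSiteNet, X: np.ndarray, batch_size: int = 100):
    """(donor, acceptor, junction) score arrays for encoded windows."""
    probs = model.predict(X, batch_size=batch_size)
    donor = probs[:, enc.CLASS_DONOR, enc.DONOR_POS]
    acceptor = probs[:, enc.CLASS_ACCEPTOR, enc.ACCEPTOR_POS]
    return donor, acceptor, np.minimum(donor, acceptor)


def evaluate(donor_scores, acceptor_scores, labels, thresholds) -> pd.DataFrame:
    """Junction- and site-level accuracy/precision/recall per threshold.

    A junction is predicted positive iff min(donor, acceptor) >= threshold;
    donor and acceptor site calls use their own scores.  ``labels`` is 1 for
    true junctions, 0 for negatives (a true junction's donor and acceptor
    are both true sites).
    """
    donor = np.asarray(donor_scores, dtype=float)
    acceptor = np.asarray(acceptor_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    junction = np.minimum(donor, acceptor)
    rows = []
    for t in thresholds:
        row = {"threshold": float(t)}
        for name, s in (("junction", junction), ("donor", donor), ("acceptor", acceptor)):
            pred = s >= t
            tp = int(np.sum(pred & (labels == 1)))
            fp = int(np.sum(pred & (labels == 0)))
            fn = int(np.sum(~pred & (labels == 1)))
            tn = int(np.sum(~pred & (labels == 0)))
            row[f"{name}_accuracy"] = (tp + tn) / len(labels)
            row[f"{name}_precision"] = tp / (tp + fp) if tp + fp else float("nan")
            row[f"{name}_recall"] = tp / (tp + fn) if tp + fn else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
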