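"""Loss, optimizer and training loop for the multi-task network.

The total loss is ``L_total = alpha * L_all + beta * L_receip`` where each
term is the negative log likelihood of the true per-pixel label under the
softmax output of the corresponding decoder, normalized per pixel so the
weights are independent of image and batch size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from icgflow.segmentation.config import SegConfig
from icgflow.segmentation.net import MultiTaskUNet

__all__ = ["SegSample", "SegPrediction", "multitask_loss", "train", "Adam"]

log = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class SegSample:
    """One training example: grayscale image + the two binary label maps."""

    image: np.ndarray
    label_all: np.ndarray
    label_receip: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.label_all = np.asarray(self.label_all, bool)
        self.label_receip = np.asarray(self.label_receip, bool)
        if not (self.image.shape == self.label_all.shape == self.label_receip.shape):
            raise ValueError("image and label shapes must match")
        if np.any(self.label_receip & ~self.label_all):
            raise ValueError("recipient label must be a subset of the all-vessel label")


@dataclass
class SegPrediction:
    """Per-pixel foreground probabilities for the two heads."""

    prob_all: np.ndarray
    prob_receip: np.ndarray
    threshold: float = 0.5

    @property
    def mask_all(self) -> np.ndarray:
        return self.prob_all >= self.threshold

    @property
    def mask_receip(self) -> np.ndarray:
        return self.prob_receip >= self.threshold


def _nll(prob_fg: np.ndarray, label: np.ndarray) -> float:
    """-mean_x log p(x; l(x)) for a foreground-probability map."""
    p_true = np.where(label, prob_fg, 1.0 - prob_fg)
    n_clamped = int(np.sum(p_true < _EPS))
    if n_clamped:
        log.warning("clamped %d zero-probability pixels in NLL", n_clamped)
    return float(-np.mean(np.log(np.clip(p_true, _EPS, 1.0))))


def multitask_loss(pred: SegPrediction, sample: SegSample,
                   alpha: float = 1.0, beta: float = 1.0) -> float:
    """Weighted sum of the two per-head NLL losses (nonnegative scalar)."""
    if pred.prob_all.shape != sample.label_all.shape:
        raise ValueError("prediction and sample shapes must match")
    return (alpha * _nll(pred.prob_all, sample.label_all)
            + beta * _nll(pred.prob_receip, sample.label_receip))


def _softmax2(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over the class axis of (N, 2, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grad(logits: np.ndarray, labels: np.ndarray, weight: float):
    """NLL of (N, 2, H, W) logits vs (N, H, W) bool labels, and d/dlogits."""
    p = _softmax2(logits)
    n, _, h, w = logits.shape
    onehot = np.stack([~labels, labels], axis=1).astype(np.float32)
    p_true = (p * onehot).sum(axis=1)
    loss = float(-np.mean(np.log(np.clip(p_true, _EPS, 1.0))))
    grad = weight * (p - onehot) / (n * h * w)
    return weight * loss, grad.astype(np.float32)


class Adam:
    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Standardize one grayscale image to zero mean and unit variance.

    Removes acquisition-dependent brightness and contrast so the network
    sees comparable inputs regardless of exposure.
    """
    x = np.asarray(image, np.float32)
    if x.max() > 1.0:
        x = x / np.float32(255.0)
    return (x - x.mean()) / (x.std() + np.float32(1e-6))


def _stack(samples: list[SegSample]):
    x = np.stack([normalize_image(s.image) for s in samples])
    return (x[:, None], np.stack([s.label_all for s in samples]),
            np.stack([s.label_receip for s in samples]))


def train(model: MultiTaskUNet, samples: list[SegSample],
          config: SegConfig | None = None) -> tuple[MultiTaskUNet, dict]:
    """Train with Adam under the configured step learning-rate schedule.

    Each iteration draws a batch (with replacement when the dataset is
    smaller than the batch size) from a generator seeded by
    ``config.seed``, so a fixed seed reproduces the loss trace exactly.
    Returns the model and a history dict with per-iteration loss and
    learning rate. Diverging (non-finite) loss aborts with a diagnostic.
    """
    config = config or SegConfig()
    if len(samples) < 2:
        raise ValueError("training needs at least 2 samples")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr_at(0))
    losses, lrs = [], []
    n = len(samples)
    for it in range(config.total_iterations):
        opt.lr = config.lr_at(it)
        idx = rng.choice(n, size=config.batch_size, replace=n < config.batch_size)
        x, la, lr_ = _stack([samples[i] for i in idx])
        logits_all, logits_receip = model.forward(x)
        loss_a, grad_a = _loss_and_grad(logits_all, la, config.alpha)
        loss_r, grad_r = _loss_and_grad(logits_receip, lr_, config.beta)
        loss = loss_a + loss_r
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}: loss={loss}")
        model.backward(grad_a, grad_r)
        opt.step()
        losses.append(loss)
        lrs.append(opt.lr)
        if it % 25 == 0:
            log.info("iteration %d: loss=%.4f lr=%g", it, loss, opt.lr)
    return model, {"loss": np.asarray(losses), "lr": np.asarray(lrs)}
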