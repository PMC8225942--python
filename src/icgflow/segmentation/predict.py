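"""Inference with optional five-view test-time averaging."""

from __future__ import annotations

import numpy as np

from icgflow.segmentation.augment import TTA_VIEWS
from icgflow.segmentation.net import MultiTaskUNet
from icgflow.segmentation.train import SegPrediction, _softmax2, normalize_image

__all__ = ["predict", "predict_with_tta"]


def _pad_to_multiple(img: np.ndarray, div: int):
    h, w = img.shape
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


def _forward_probs(model: MultiTaskUNet, image: np.ndarray):
    """Foreground probability maps for one image, padded as needed."""
    img = normalize_image(image)
    img, (h, w) = _pad_to_multiple(img, 2 ** model.depth)
    model.set_training(False)
    try:
        la, lr = model.forward(img[None, None])
    finally:
        model.set_training(True)
    pa = _softmax2(la)[0, 1, :h, :w]
    pr = _softmax2(lr)[0, 1, :h, :w]
    return pa, pr


def predict(model: MultiTaskUNet, image: np.ndarray,
            threshold: float = 0.5) -> SegPrediction:
    """Single-view prediction (no augmentation)."""
    pa, pr = _forward_probs(model, image)
    return SegPrediction(pa, pr, threshold)


def predict_with_tta(model: MultiTaskUNet, image: np.ndarray,
                     threshold: float = 0.5) -> SegPrediction:
    """Average the probabilities of five flip/rotation views.

    Each view (identity, horizontal, vertical, diagonal flip, 180-degree
    rotation) is predicted and mapped back to the original orientation
    before averaging, which preserves the [0, 1] range and per-pixel
    normalization.
    """
    img = np.asarray(image)
    acc_a = np.zeros(img.shape, np.float64)
    acc_r = np.zeros(img.shape, np.float64)
    for view in TTA_VIEWS.values():
        pa, pr = _forward_probs(model, view(img))
        acc_a += view(pa)  # involutions: the view is its own inverse
        acc_r += view(pr)
    k = len(TTA_VIEWS)
    return SegPrediction(acc_a / k, acc_r / k, threshold)
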