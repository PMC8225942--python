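"""Flip-based augmentation for training and test-time averaging.

Training augmentation turns every labeled image into four: the original
plus horizontal, vertical and diagonal (transpose) flips, with labels
flipped identically. Test-time augmentation predicts five views — the same
four plus a 180-degree rotation — and averages the probabilities after
mapping each view back to the original orientation. Every view is an
involution, so it is its own inverse.
"""

from __future__ import annotations

import numpy as np

__all__ = ["augment_fourfold", "TTA_VIEWS", "AUG_VIEWS"]

#: name -> (transform, inverse); all involutions here.
AUG_VIEWS = {
    "identity": np.ascontiguousarray,
    "horizontal": lambda a: np.ascontiguousarray(np.fliplr(a)),
    "vertical": lambda a: np.ascontiguousarray(np.flipud(a)),
    "diagonal": lambda a: np.ascontiguousarray(np.swapaxes(a, -2, -1)),
}

TTA_VIEWS = dict(AUG_VIEWS)
TTA_VIEWS["rot180"] = lambda a: np.ascontiguousarray(a[::-1, ::-1])


def augment_fourfold(samples):
    """Expand samples x4: original + horizontal, vertical, diagonal flips.

    Accepts a list of :class:`~icgflow.segmentation.train.SegSample`;
    duplicates arising from symmetric images are kept (the count is always
    exactly 4x the input).
    """
    from icgflow.segmentation.train import SegSample

    out = []
    for s in samples:
        for view in AUG_VIEWS.values():
            out.append(SegSample(view(s.image), view(s.label_all), view(s.label_receip)))
    return out
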