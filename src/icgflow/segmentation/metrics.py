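"""Overlap metrics for binary segmentations.

Dice = 2|A n B| / (|A| + |B|); Jaccard = |A n B| / |A u B|. The two are
linked by Dice = 2J / (1 + J), so Dice >= Jaccard always. Two empty masks
agree perfectly and score 1.0 by convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice", "jaccard"]


def _check(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    for m in (a, b):
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary")
    return a.astype(bool), b.astype(bool)


def dice(mask_a, mask_b) -> float:
    a, b = _check(mask_a, mask_b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def jaccard(mask_a, mask_b) -> float:
    a, b = _check(mask_a, mask_b)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)
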