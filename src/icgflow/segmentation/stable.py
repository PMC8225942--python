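"""Selection of the stable (fully washed-in) frame for segmentation.

Segmentation runs on frames where the dye has saturated the vessels and the
brightness no longer changes; this picks the earliest such frame.
"""

from __future__ import annotations

import warnings

import numpy as np

from icgflow.io import ICGVideo

__all__ = ["select_stable_frame"]


def select_stable_frame(video: ICGVideo, mask: np.ndarray | None = None,
                        frac: float = 0.99, window: int = 5,
                        smooth: int = 5) -> int:
    """Earliest frame index at which mean brightness has stopped rising.

    The frame-mean brightness trace (over ``mask`` if given, else the
    whole frame) is smoothed with a ``smooth``-frame moving average and
    the first frame whose value reaches ``frac`` of the dark-to-plateau
    range is returned: from there on the wash-in has essentially completed.
    The initial dark phase is also "unchanging" but is never selected. A
    constant video returns 0; a video still rising within ``window``
    frames of its end never stabilizes and returns the last frame with a
    warning.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if mask is not None:
        means = video.frames[:, np.asarray(mask, bool)].mean(axis=1)
    else:
        means = video.frames.reshape(video.n_frames, -1).mean(axis=1)
    if smooth > 1:
        from scipy.ndimage import uniform_filter1d

        means = uniform_filter1d(means.astype(float), smooth, mode="nearest")
    rng_ = float(np.ptp(means))
    if rng_ == 0:
        return 0
    idx = int(np.argmax(means >= means.min() + frac * rng_))
    if video.n_frames - idx < min(window, video.n_frames - 1):
        warnings.warn("brightness never stabilizes; returning the last frame",
                      stacklevel=2)
        return video.n_frames - 1
    return idx
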