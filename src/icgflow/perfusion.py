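"""Time-luminance curves, delay times and time-to-peak perfusion maps.

The dye bolus reaches different vessel segments at different times, so the
time at which each pixel (or region of interest) first attains its maximum
brightness — the delay time, or time-to-peak — summarizes the perfusion
sequence. Painting time-to-peak through a red -> blue-purple color ramp
reproduces the familiar angiography perfusion map: early-filling segments
red, late-filling segments blue-purple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from skimage.draw import polygon as _draw_polygon

from icgflow.io import ICGVideo

__all__ = [
    "ROI",
    "LuminanceCurve",
    "PerfusionMap",
    "luminance_curve",
    "delay_time",
    "perfusion_color_map",
    "colorbar_lookup",
    "default_colorbar",
    "SMOOTHING_FRAMES",
]

#: Centered moving-average width used before peak detection (0.2 s at 25 fps).
SMOOTHING_FRAMES = 5


@dataclass
class ROI:
    """A region of interest given as a polygon or an explicit pixel mask."""

    id: str
    polygon: np.ndarray | None = None  # (N, 2) of (x, y)
    mask: np.ndarray | None = None
    label: str = ""

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, bool)
            if m.shape != shape:
                raise ValueError("ROI mask shape mismatch")
        else:
            poly = np.asarray(self.polygon, float)
            if poly.ndim != 2 or poly.shape[0] < 3:
                raise ValueError("ROI polygon needs at least 3 vertices")
            rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape)
            m = np.zeros(shape, bool)
            m[rr, cc] = True
        if not m.any():
            raise ValueError(f"ROI {self.id!r} covers no pixels")
        return m

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        return cls(id=str(d["id"]), polygon=np.asarray(d["polygon"], float),
                   label=d.get("label", ""))


@dataclass
class LuminanceCurve:
    """Mean ROI brightness per frame against time (seconds from frame 0)."""

    times: np.ndarray
    values: np.ndarray
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values,
                             "roi_id": self.roi_id})


def _smooth(values: np.ndarray, width: int = SMOOTHING_FRAMES, axis: int = -1) -> np.ndarray:
    """Centered moving average with edge replication."""
    if width <= 1:
        return np.asarray(values, float)
    from scipy import ndimage as ndi

    kernel_size = [1] * np.asarray(values).ndim
    kernel_size[axis] = width
    return ndi.uniform_filter(np.asarray(values, float), size=kernel_size, mode="nearest")


def luminance_curve(video: ICGVideo, roi: ROI | np.ndarray,
                    smooth_width: int = 0) -> LuminanceCurve:
    """Mean brightness of the ROI pixels at every frame.

    ``smooth_width`` > 1 applies a centered moving average (frames);
    the default returns the raw trace.
    """
    if isinstance(roi, ROI):
        m = roi.pixel_mask(video.frame_shape)
        roi_id = roi.id
    else:
        m = np.asarray(roi, bool)
        roi_id = ""
        if not m.any():
            raise ValueError("ROI mask is empty")
    values = video.frames[:, m].mean(axis=1)
    if smooth_width > 1:
        values = _smooth(values, smooth_width)
    return LuminanceCurve(video.times, values, roi_id)


def delay_time(curve: LuminanceCurve, smooth_width: int = SMOOTHING_FRAMES
               ) -> tuple[float, bool]:
    """Time (s) of the first frame attaining the curve's maximum brightness.

    The curve is smoothed with a centered moving average before the argmax
    (raw traces of noisy video make the peak location unstable); ties break
    to the earliest frame. Returns ``(seconds, flat_flag)``; a flat curve
    yields 0 s with the flag set.
    """
    if len(curve.values) < 2:
        raise ValueError("delay time needs at least 2 samples")
    sm = _smooth(curve.values, smooth_width)
    if np.ptp(sm) == 0:
        warnings.warn("flat luminance curve; delay time set to 0 s", stacklevel=2)
        return float(curve.times[0]), True
    return float(curve.times[int(np.argmax(sm))]), False


@dataclass
class PerfusionMap:
    """Per-pixel time-to-peak (s) on the vessel mask plus its RGB rendering."""

    ttp: np.ndarray
    rgb: np.ndarray
    mask: np.ndarray
    t_lo: float
    t_hi: float


def default_colorbar(n: int = 256) -> np.ndarray:
    """Red -> yellow -> green -> cyan -> blue -> purple ramp, shape (n, 3) in [0, 1].

    Early-arriving pixels map to red, late-arriving to blue-purple. The ramp
    is qualitative; the commercial software's exact LUT is unknown.
    """
    cmap = LinearSegmentedColormap.from_list(
        "perfusion",
        [(1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 1, 1), (0, 0, 1), (0.5, 0, 0.5)],
    )
    return cmap(np.linspace(0, 1, n))[:, :3]


def perfusion_color_map(video: ICGVideo, mask: np.ndarray,
                        smooth_width: int = SMOOTHING_FRAMES,
                        colorbar: np.ndarray | None = None) -> PerfusionMap:
    """Per-pixel delay-time (time-to-peak) map rendered through the color ramp.

    Each vessel pixel's trace is smoothed and its first-maximum time taken
    (the same computation as :func:`delay_time` applied pixelwise), then
    linearly mapped onto the ramp between the 1st and 99th percentiles of
    time-to-peak within the mask. Background pixels are black.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("vessel mask is empty")
    if video.n_frames < 2:
        raise ValueError("perfusion map needs at least 2 frames")
    traces = video.frames[:, mask].astype(float)  # (T, N)
    sm = _smooth(traces, smooth_width, axis=0)
    peak_idx = np.argmax(sm, axis=0)  # first max per pixel
    ttp_vals = video.times[peak_idx]

    ttp = np.zeros(video.frame_shape, float)
    ttp[mask] = ttp_vals
    t_lo, t_hi = np.percentile(ttp_vals, [1, 99])
    if t_hi <= t_lo:
        t_hi = t_lo + 1e-9
    pos = np.clip((ttp_vals - t_lo) / (t_hi - t_lo), 0.0, 1.0)

    bar = default_colorbar() if colorbar is None else np.asarray(colorbar, float)
    idx = np.round(pos * (len(bar) - 1)).astype(int)
    rgb = np.zeros(video.frame_shape + (3,), float)
    rgb[mask] = bar[idx]
    return PerfusionMap(ttp, rgb, mask, float(t_lo), float(t_hi))


def colorbar_lookup(rgb_value, colorbar: np.ndarray | None = None
                    ) -> tuple[float, bool]:
    """Relative ramp position of an RGB color (nearest entry, Euclidean).

    Mirrors reading a perfusion color against the printed colorbar to
    recover relative arrival time. Returns ``(position in [0, 1],
    ambiguous_flag)``; ties go to the earliest position and are flagged.
    """
    bar = default_colorbar() if colorbar is None else np.asarray(colorbar, float)
    rgb = np.asarray(rgb_value, float)
    d2 = ((bar - rgb[None, :]) ** 2).sum(axis=1)
    best = float(d2.min())
    hits = np.nonzero(np.isclose(d2, best, rtol=0, atol=1e-12))[0]
    pos = hits[0] / (len(bar) - 1)
    return float(pos), len(hits) > 1
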