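"""Readers and writers for angiography videos, masks and ROI definitions.

The in-memory video container is a plain frame stack: ICG-VA recordings are
8-bit grayscale sequences (the acquisition here is modeled after 25 frames/s
black-and-white angiography video). Inputs may be a directory of numbered
image frames, a multi-page TIFF, a ``.npy`` stack, or any single-file
container imageio can open in the running environment; color frames are
reduced to grayscale by the Rec. 601 luma transform.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["ICGVideo", "read_video", "write_video", "read_mask", "write_mask",
           "read_rois", "write_rois", "to_gray"]

DEFAULT_FPS = 25.0

_FRAME_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to 8-bit grayscale with the luma transform."""
    if frame.ndim == 2:
        g = frame
    elif frame.ndim == 3:
        rgb = frame[..., :3].astype(float)
        g = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    else:
        raise ValueError(f"unsupported frame shape {frame.shape}")
    if g.dtype != np.uint8:
        g = np.clip(np.round(g), 0, 255).astype(np.uint8)
    return g


@dataclass
class ICGVideo:
    """Ordered grayscale frame stack with its frame rate.

    ``frames`` has shape (T, H, W), dtype uint8; ``fps`` is frames per second.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] < 1:
            raise ValueError("video has zero frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.dtype != np.uint8:
            self.frames = np.clip(np.round(self.frames.astype(float)), 0, 255).astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds, measured from the first frame."""
        return np.arange(self.n_frames) / self.fps

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    def __len__(self) -> int:
        return self.n_frames


def _numeric_key(p: Path):
    nums = re.findall(r"\d+", p.stem)
    return (int(nums[-1]) if nums else 0, p.name)


def _read_fps_sidecar(path: Path) -> float | None:
    for cand in (path / "meta.json" if path.is_dir() else None,
                 path.with_suffix(path.suffix + ".meta.json") if not path.is_dir() else None):
        if cand is not None and cand.exists():
            meta = json.loads(cand.read_text())
            if "fps" in meta:
                return float(meta["fps"])
    return None


def read_video(path, fps: float | None = None) -> ICGVideo:
    """Read a video from a frame directory, TIFF stack, NPY stack or container.

    ``fps`` overrides any sidecar metadata; when neither is present the
    angiography default of 25 frames/s is assumed.
    """
    path = Path(path)
    sidecar_fps = _read_fps_sidecar(path)
    if path.is_dir():
        files = sorted((p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS),
                       key=_numeric_key)
        if not files:
            raise IOError(f"no image frames found in {path}")
        frames = np.stack([to_gray(iio.imread(f)) for f in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = np.stack([to_gray(f) for f in stack])
    elif path.suffix.lower() == ".npy":
        frames = np.load(path)
        if frames.ndim == 2:
            frames = frames[None]
        frames = np.stack([to_gray(f) for f in frames])
    else:
        try:
            raw = iio.imread(path)
            props = None
            try:
                meta = iio.immeta(path)
                props = meta.get("fps")
            except Exception:
                props = None
            if props and fps is None and sidecar_fps is None:
                sidecar_fps = float(props)
        except Exception as exc:  # no suitable plugin / unreadable container
            raise IOError(f"cannot read video container {path}: {exc}") from exc
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim == 4 or (raw.ndim == 3 and raw.shape[-1] in (3, 4) and raw.shape[0] not in (3, 4)):
            # (T,H,W,C) or single RGB frame
            if raw.ndim == 3:
                raw = raw[None]
            frames = np.stack([to_gray(f) for f in raw])
        else:
            frames = np.stack([to_gray(f) for f in raw])
    if frames.shape[0] == 0:
        raise IOError(f"zero frames read from {path}")
    return ICGVideo(frames, fps=fps or sidecar_fps or DEFAULT_FPS)


def write_video(video: ICGVideo, path) -> Path:
    """Write a video as a numbered PNG directory, TIFF stack or NPY stack."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, video.frames)
        Path(str(path) + ".meta.json").write_text(json.dumps({"fps": video.fps}))
    elif path.suffix.lower() == ".npy":
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path, video.frames)
        Path(str(path) + ".meta.json").write_text(json.dumps({"fps": video.fps}))
    else:
        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(4, len(str(video.n_frames)))
        for i, frame in enumerate(video.frames):
            iio.imwrite(path / f"frame_{i:0{ndigits}d}.png", frame)
        (path / "meta.json").write_text(json.dumps({"fps": video.fps}))
    return path


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG; any nonzero pixel is foreground."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return img > 0


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_rois(path) -> list[dict]:
    """Read ROI definitions: a JSON list of ``{"id", "polygon": [[x, y], ...]}``."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("rois", [data])
    return data


def write_rois(rois: list[dict], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(rois, indent=2))
    return path
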