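"""Synthetic ICG angiography phantoms with exact ground truth.

Clinical ICG-VA recordings show a vessel tree that turns from dark to bright
as the dye bolus washes in; the wash-in front travels along each vessel, so
per-pixel arrival time encodes the blood-flow direction. This module builds
that observable from known primitives — a random vessel tree, a per-pixel
arrival-time map derived from centerline arc-length, a sigmoidal brightness
ramp, additive sensor noise — and keeps every latent quantity as ground
truth so the segmentation, registration, optical-flow and perfusion stages
can each be verified without clinical data.

Direction encoding (three categories observed after bypass surgery):

- ``forward``  — arrival increases with centerline arc-length;
- ``reverse``  — arrival decreases with arc-length;
- ``middle_to_both_sides`` — arrival is V-shaped around an anastomosis
  point, the dye entering at the graft site and running toward both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.spatial import cKDTree
from scipy.ndimage import binary_dilation
from skimage.draw import line as _draw_line
from skimage.morphology import disk
from skimage.transform import ProjectiveTransform, warp

from icgflow.io import ICGVideo

__all__ = [
    "VesselTree",
    "WashInSpec",
    "GroundTruth",
    "generate_vessel_tree",
    "make_arrival_map",
    "generate_icg_video",
    "generate_pre_post_pair",
    "generate_seg_dataset",
    "similarity_homography",
    "DIRECTIONS",
]

DIRECTIONS = ("forward", "reverse", "middle_to_both_sides")


# ----------------------------------------------------------------------------
# vessel tree
# ----------------------------------------------------------------------------

@dataclass
class VesselTree:
    """Binary vessel raster plus per-branch ordered centerlines.

    ``centerlines[i]`` is an (N, 2) array of (row, col) pixels ordered along
    the branch; ``branch_graph[i]`` is ``(parent_branch, attach_index)`` with
    ``(-1, -1)`` for the root. Branch 0 is the recipient vessel.
    """

    mask: np.ndarray
    recipient_mask: np.ndarray
    centerlines: list[np.ndarray]
    branch_graph: list[tuple[int, int]]
    widths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        self.recipient_mask = np.asarray(self.recipient_mask, bool)
        if self.mask.shape != self.recipient_mask.shape:
            raise ValueError("mask and recipient_mask shapes differ")
        if np.any(self.recipient_mask & ~self.mask):
            raise ValueError("recipient_mask must be a subset of mask")
        for cl in self.centerlines:
            if np.any(~self.mask[cl[:, 0], cl[:, 1]]):
                raise ValueError("centerline pixels must lie inside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def centerline(self) -> np.ndarray:
        """Recipient (main branch) centerline, ordered along the vessel."""
        return self.centerlines[0]


def _rasterize_polyline(points: np.ndarray) -> np.ndarray:
    """8-connected pixel chain through the given (row, col) vertices."""
    segs = []
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
        seg = np.column_stack([rr, cc])
        if segs:
            seg = seg[1:]  # drop shared vertex
        segs.append(seg)
    return np.concatenate(segs) if segs else points.astype(int)


def generate_vessel_tree(seed: int, shape: tuple[int, int] = (128, 128),
                         n_branches: int = 3) -> VesselTree:
    """Generate a random vessel tree: one main (recipient) vessel spanning
    the frame left to right plus side branches of varying width.

    Deterministic for a fixed ``seed``. The main vessel's column coordinate
    is monotone and each side branch's row coordinate is monotone, which
    guarantees non-self-intersecting 8-connected centerlines.
    """
    H, W = shape
    if H < 64 or W < 64:
        raise ValueError("frame must be at least 64x64 to place a vessel tree")
    if n_branches < 1:
        raise ValueError("need at least one branch")
    rng = np.random.default_rng(seed)
    margin = 6

    # main vessel: smooth curve with monotone column coordinate
    n_ctrl = 6
    cols = np.linspace(margin, W - 1 - margin, n_ctrl).round().astype(int)
    row0 = rng.integers(H // 3, 2 * H // 3)
    rows = [row0]
    for _ in range(n_ctrl - 1):
        step = rng.integers(-H // 8, H // 8 + 1)
        rows.append(int(np.clip(rows[-1] + step, margin, H - 1 - margin)))
    main = _rasterize_polyline(np.column_stack([rows, cols]))

    centerlines = [main]
    branch_graph: list[tuple[int, int]] = [(-1, -1)]
    widths = [int(rng.integers(2, 4))]

    for _ in range(n_branches - 1):
        attach = int(rng.integers(len(main) // 5, 4 * len(main) // 5))
        r0, c0 = main[attach]
        direction = rng.choice([-1, 1])
        # monotone row path toward the frame edge with lateral drift
        length = int(rng.integers(H // 4, H // 2))
        r_end = int(np.clip(r0 + direction * length, margin, H - 1 - margin))
        if abs(r_end - r0) < 8:  # too close to an edge: flip direction
            direction = -direction
            r_end = int(np.clip(r0 + direction * length, margin, H - 1 - margin))
        c_mid = int(np.clip(c0 + rng.integers(-W // 8, W // 8 + 1), margin, W - 1 - margin))
        c_end = int(np.clip(c_mid + rng.integers(-W // 8, W // 8 + 1), margin, W - 1 - margin))
        r_mid = (r0 + r_end) // 2
        pts = np.array([[r0, c0], [r_mid, c_mid], [r_end, c_end]])
        branch = _rasterize_polyline(pts)
        centerlines.append(branch)
        branch_graph.append((0, attach))
        widths.append(int(rng.integers(1, 3)))

    mask = np.zeros(shape, bool)
    tubes = []
    for cl, w in zip(centerlines, widths):
        tube = np.zeros(shape, bool)
        tube[cl[:, 0], cl[:, 1]] = True
        tube = binary_dilation(tube, structure=disk(w))
        tubes.append(tube)
        mask |= tube
    recipient = tubes[0]
    return VesselTree(mask, recipient, centerlines, branch_graph, widths)


# ----------------------------------------------------------------------------
# wash-in dynamics
# ----------------------------------------------------------------------------

def _arc_length(cl: np.ndarray) -> np.ndarray:
    d = np.sqrt(((np.diff(cl, axis=0)) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(d)])


def make_arrival_map(tree: VesselTree, direction: str = "forward",
                     transit_time: float = 4.0, start_time: float = 0.5,
                     anastomosis_frac: float = 0.5) -> np.ndarray:
    """Per-pixel dye arrival time (s) encoding the requested flow direction.

    Arrival is a linear function of arc-length along the main centerline
    (increasing for ``forward``, decreasing for ``reverse``, V-shaped around
    the anastomosis located at ``anastomosis_frac`` of the arc for
    ``middle_to_both_sides``). Side branches fill outward from their
    attachment point at the same front speed. Every mask pixel inherits the
    arrival of its nearest centerline pixel; background is left at 0.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    main = tree.centerlines[0]
    s = _arc_length(main)
    L = s[-1]
    speed = L / transit_time  # px/s front speed

    if direction == "forward":
        t_main = start_time + s / speed
    elif direction == "reverse":
        t_main = start_time + (L - s) / speed
    else:
        s_mid = anastomosis_frac * L
        t_main = start_time + np.abs(s - s_mid) / speed

    pts = [main]
    times = [t_main]
    for cl, (parent, attach) in zip(tree.centerlines[1:], tree.branch_graph[1:]):
        sb = _arc_length(cl)
        times.append(times[parent][attach] + sb / speed)
        pts.append(cl)
    pts = np.concatenate(pts)
    times = np.concatenate(times)
    # branches overlap the parent near their attachment: dye reaches a
    # shared pixel at the earlier of the candidate times
    order = np.argsort(times, kind="stable")
    pts_sorted = pts[order]
    _, first = np.unique(pts_sorted, axis=0, return_index=True)
    pts_u = pts_sorted[first]
    times_u = times[order][first]

    arrival = np.zeros(tree.shape, float)
    rr, cc = np.nonzero(tree.mask)
    _, idx = cKDTree(pts_u).query(np.column_stack([rr, cc]))
    arrival[rr, cc] = times_u[idx]
    return arrival


@dataclass
class WashInSpec:
    """Photometric and temporal parameters of the dark-to-bright wash-in.

    Brightness at a vessel pixel with arrival time ``a`` follows
    ``baseline + (peak_brightness - baseline) * ramp((t - a) / rise_time)``
    where ``ramp`` is a cubic smoothstep: 0 before the dye arrives, a smooth
    sigmoidal rise over ``rise_time`` seconds, then an exact plateau — so
    time-to-peak is exactly ``a + rise_time``. Gaussian sensor noise of
    standard deviation ``noise_sd`` is added and the result clipped to the
    8-bit range.
    """

    arrival_map: np.ndarray
    rise_time: float = 1.0
    peak_brightness: float = 200.0
    baseline: float = 20.0
    noise_sd: float = 2.0
    fps: float = 25.0
    duration: float | None = None  # default: cover max arrival + rise + 1 s
    direction: str | None = None
    noise_seed: int = 0

    def __post_init__(self) -> None:
        self.arrival_map = np.asarray(self.arrival_map, float)
        if np.any(self.arrival_map < 0):
            raise ValueError("arrival times must be nonnegative")
        if not self.baseline < self.peak_brightness:
            raise ValueError("baseline must be below peak_brightness")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.rise_time < 0 or self.noise_sd < 0:
            raise ValueError("rise_time and noise_sd must be nonnegative")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class GroundTruth:
    """Latent state of a synthetic acquisition, for verifying the pipeline."""

    arrival_map: np.ndarray
    time_to_peak: np.ndarray
    mask: np.ndarray
    recipient_mask: np.ndarray
    true_direction: dict
    true_homography: np.ndarray | None = None
    arrival_map_post: np.ndarray | None = None
    mask_post: np.ndarray | None = None
    recipient_mask_post: np.ndarray | None = None

    def save(self, outdir) -> None:
        """Write the JSON (homography, directions) + float TIFF (arrival) record."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"true_direction": self.true_direction}
        if self.true_homography is not None:
            meta["true_homography"] = np.asarray(self.true_homography).tolist()
        (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=2))
        tifffile.imwrite(outdir / "arrival_map.tif", self.arrival_map.astype(np.float32))
        if self.arrival_map_post is not None:
            tifffile.imwrite(outdir / "arrival_map_post.tif",
                             self.arrival_map_post.astype(np.float32))


def generate_icg_video(tree: VesselTree, spec: WashInSpec) -> tuple[ICGVideo, GroundTruth]:
    """Render the wash-in video for a vessel tree and return it with truth.

    Background pixels stay at baseline (+noise); vessel pixels ramp from
    baseline to peak starting at their arrival time. Deterministic for a
    fixed spec (noise is seeded by ``spec.noise_seed``).
    """
    if not tree.mask.any():
        raise ValueError("vessel mask is empty")
    duration = spec.duration
    if duration is None:
        duration = float(spec.arrival_map[tree.mask].max() + spec.rise_time + 1.0)
    n_frames = int(round(duration * spec.fps))
    if n_frames < 2:
        raise ValueError("duration * fps must give at least 2 frames")

    t = np.arange(n_frames) / spec.fps
    rise = max(spec.rise_time, 1.0 / spec.fps * 1e-6)  # guard rise_time -> 0
    # (T, H, W) ramp only on mask pixels to keep memory in check
    rr, cc = np.nonzero(tree.mask)
    arr = spec.arrival_map[rr, cc]
    ramp = _smoothstep((t[:, None] - arr[None, :]) / rise)  # (T, Nmask)

    frames = np.full((n_frames,) + tree.shape, spec.baseline, dtype=np.float32)
    frames[:, rr, cc] += (spec.peak_brightness - spec.baseline) * ramp.astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.noise_seed)
        frames += rng.normal(0.0, spec.noise_sd, frames.shape).astype(np.float32)
    frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        arrival_map=spec.arrival_map.copy(),
        time_to_peak=np.where(tree.mask, spec.arrival_map + spec.rise_time, 0.0),
        mask=tree.mask.copy(),
        recipient_mask=tree.recipient_mask.copy(),
        true_direction={"pre": spec.direction},
    )
    return ICGVideo(frames, fps=spec.fps), truth


def generate_seg_dataset(seed: int, n: int, shape: tuple[int, int] = (64, 64)):
    """Labeled image set for segmentation training: stable-phase frames.

    Each sample renders the fully washed-in state of a random vessel tree
    with randomized photometry (baseline, peak, sensor noise) on top of a
    smooth random illumination field, so plain global thresholding is not
    sufficient. Labels are the tree's all-vessel and recipient masks.
    """
    from scipy.ndimage import gaussian_filter

    from icgflow.segmentation.train import SegSample

    rng = np.random.default_rng(seed)
    samples = []
    for k in range(n):
        tree = generate_vessel_tree(int(rng.integers(0, 2**31 - 1)), shape,
                                    n_branches=int(rng.integers(2, 5)))
        baseline = rng.uniform(10, 50)
        peak = rng.uniform(110, 230)
        noise_sd = rng.uniform(1, 5)
        illum = gaussian_filter(rng.normal(0, 1, shape), 8) * rng.uniform(5, 25)
        img = np.full(shape, baseline) + illum
        img[tree.mask] += (peak - baseline)
        img += rng.normal(0, noise_sd, shape)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        samples.append(SegSample(img, tree.mask, tree.recipient_mask))
    return samples


# ----------------------------------------------------------------------------
# pre/post pairs under a known geometric transform
# ----------------------------------------------------------------------------

def similarity_homography(shape: tuple[int, int], rotation_deg: float = 0.0,
                          scale: float = 1.0,
                          translation: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """3x3 homography of a similarity about the image center, last element 1.

    ``translation`` is (tx, ty) in pixels with x = column, y = row.
    """
    H, W = shape
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    th = np.deg2rad(rotation_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[scale * c, -scale * s, 0.0],
                  [scale * s, scale * c, 0.0],
                  [0.0, 0.0, 1.0]])
    T1 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    T2 = np.array([[1, 0, cx + translation[0]], [0, 1, cy + translation[1]], [0, 0, 1.0]])
    M = T2 @ R @ T1
    return M / M[2, 2]


def _warp_by(img: np.ndarray, H: np.ndarray, order: int = 0) -> np.ndarray:
    tform = ProjectiveTransform(matrix=np.asarray(H, float))
    return warp(img.astype(float), tform.inverse, order=order, mode="constant",
                cval=0.0, preserve_range=True)


def generate_pre_post_pair(tree: VesselTree, spec_pre: WashInSpec,
                           spec_post: WashInSpec,
                           transform: dict | None = None
                           ) -> tuple[ICGVideo, ICGVideo, GroundTruth]:
    """Render a pre/post acquisition pair related by a known similarity.

    The postoperative geometry is the preoperative one warped by the stated
    transform (``{"rotation": deg, "scale": s, "translation": (tx, ty)}``,
    emulating microscope repositioning between acquisitions), with its own
    independent wash-in dynamics. ``true_homography`` maps preoperative to
    postoperative pixel coordinates.
    """
    transform = transform or {}
    rot = float(transform.get("rotation", 0.0))
    scale = float(transform.get("scale", 1.0))
    trans = tuple(transform.get("translation", (0.0, 0.0)))
    if abs(rot) > 45:
        raise ValueError("|rotation| must be <= 45 degrees")
    if not 0.5 <= scale <= 2.0:
        raise ValueError("scale must be within [0.5, 2]")

    Hmat = similarity_homography(tree.shape, rot, scale, trans)

    video_pre, truth_pre = generate_icg_video(tree, spec_pre)

    mask_post = _warp_by(tree.mask, Hmat, order=0) > 0.5
    recip_post = _warp_by(tree.recipient_mask, Hmat, order=0) > 0.5
    if not mask_post.any():
        raise ValueError("transform maps the vessel tree outside the frame")
    arrival_post = _warp_by(spec_post.arrival_map, Hmat, order=0)
    arrival_post[~mask_post] = 0.0

    post_tree = VesselTree.__new__(VesselTree)  # warped raster-only tree
    post_tree.mask = mask_post
    post_tree.recipient_mask = recip_post
    post_tree.centerlines = []
    post_tree.branch_graph = []
    post_tree.widths = []
    spec_post_w = WashInSpec(
        arrival_map=arrival_post, rise_time=spec_post.rise_time,
        peak_brightness=spec_post.peak_brightness, baseline=spec_post.baseline,
        noise_sd=spec_post.noise_sd, fps=spec_post.fps, duration=spec_post.duration,
        direction=spec_post.direction, noise_seed=spec_post.noise_seed + 1,
    )
    video_post, _ = generate_icg_video(post_tree, spec_post_w)

    truth = GroundTruth(
        arrival_map=spec_pre.arrival_map.copy(),
        time_to_peak=np.where(tree.mask, spec_pre.arrival_map + spec_pre.rise_time, 0.0),
        mask=tree.mask.copy(),
        recipient_mask=tree.recipient_mask.copy(),
        true_direction={"pre": spec_pre.direction, "post": spec_post.direction},
        true_homography=Hmat,
        arrival_map_post=arrival_post,
        mask_post=mask_post,
        recipient_mask_post=recip_post,
    )
    return video_pre, video_post, truth
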