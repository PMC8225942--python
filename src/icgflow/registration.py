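"""SIFT-based alignment of preoperative and postoperative vessel maps.

Microscope repositioning between the two acquisitions changes viewpoint,
zoom and framing, so before perfusion can be compared the preoperative
(moving) vessel map must be aligned to the postoperative (fixed) one.
Keypoints come from difference-of-Gaussian extrema with 128-dimensional
gradient-histogram descriptors (SIFT); candidate correspondences pass
Lowe's ratio test (nearest / second-nearest descriptor distance < 0.8);
a homography is fit robustly with RANSAC. A registration is accepted when
the warped and fixed vessel masks overlap in at least 35% of the vessel
pixels and at least 10 ratio-test correspondences support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy import ndimage as ndi
from skimage.feature import SIFT
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, SimilarityTransform, warp

__all__ = [
    "Keypoints",
    "MatchSet",
    "RegistrationError",
    "detect_sift",
    "vessel_map_for_registration",
    "match_ratio_test",
    "estimate_homography",
    "registration_success",
    "fuse_images",
    "register_masks",
    "RATIO_THRESHOLD",
    "OVERLAP_THRESHOLD",
    "MIN_CORRESPONDENCES",
]

RATIO_THRESHOLD = 0.8
OVERLAP_THRESHOLD = 0.35
MIN_CORRESPONDENCES = 10


class RegistrationError(RuntimeError):
    """Raised when a homography cannot be estimated."""


@dataclass
class Keypoints:
    """Detected keypoints with L2-normalized 128-d descriptors.

    ``xy`` holds subpixel (x, y) = (column, row) positions.
    """

    xy: np.ndarray
    scales: np.ndarray
    orientations: np.ndarray
    descriptors: np.ndarray

    def __len__(self) -> int:
        return len(self.xy)


@dataclass
class MatchSet:
    """Ratio-test surviving correspondences (moving index, fixed index, distance)."""

    pairs: np.ndarray  # (M, 2) int indices
    distances: np.ndarray
    ratio_threshold: float = RATIO_THRESHOLD

    def __len__(self) -> int:
        return len(self.pairs)


def vessel_map_for_registration(mask: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Lightly blurred float rendering of a binary vessel mask.

    DoG keypoint detection needs smooth intensity structure; raw binary
    masks have none, so the mask is Gaussian-blurred before detection.
    """
    return ndi.gaussian_filter(np.asarray(mask, float), sigma)


def detect_sift(image: np.ndarray) -> Keypoints:
    """DoG keypoints + 128-d SIFT descriptors for a single-channel image.

    A blank (constant) image yields an empty result rather than an error.
    Descriptors are L2-normalized. Deterministic for a fixed input.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("detect_sift expects a single-channel image")
    if np.ptp(img) == 0:
        return Keypoints(np.empty((0, 2)), np.empty(0), np.empty(0), np.empty((0, 128)))
    det = SIFT()
    try:
        det.detect_and_extract(img)
    except RuntimeError:  # no extrema found
        return Keypoints(np.empty((0, 2)), np.empty(0), np.empty(0), np.empty((0, 128)))
    desc = det.descriptors.astype(float)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    desc = desc / norms
    xy = det.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return Keypoints(xy, det.scales.astype(float), det.orientations.astype(float), desc)


def match_ratio_test(desc_a: np.ndarray, desc_b: np.ndarray,
                     ratio: float = RATIO_THRESHOLD) -> MatchSet:
    """Nearest-neighbour matching with Lowe's ratio test.

    For each descriptor in A the two nearest neighbours in B (Euclidean)
    are found; the match is kept iff d1/d2 < ratio (strict). Sets with
    fewer than two candidates in B yield no matches (the ratio is
    undefined without a second neighbour).
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    a = np.asarray(desc_a, float)
    b = np.asarray(desc_b, float)
    if len(a) == 0 or len(b) < 2:
        return MatchSet(np.empty((0, 2), int), np.empty(0), ratio)
    d = cdist(a, b)
    nn = np.argsort(d, axis=1)[:, :2]
    d1 = d[np.arange(len(a)), nn[:, 0]]
    d2 = d[np.arange(len(a)), nn[:, 1]]
    keep = d1 < ratio * d2
    pairs = np.column_stack([np.nonzero(keep)[0], nn[keep, 0]])
    return MatchSet(pairs, d1[keep], ratio)


def _fit(model_cls, src, dst):
    tform = model_cls.from_estimate(src, dst)
    if not tform or not np.all(np.isfinite(tform.params)):
        return None
    return tform


def estimate_homography(matches: MatchSet, kp_moving: Keypoints | np.ndarray,
                        kp_fixed: Keypoints | np.ndarray,
                        residual_threshold: float = 3.0,
                        max_trials: int = 2000,
                        seed: int = 0,
                        model: str = "similarity") -> tuple[np.ndarray, np.ndarray]:
    """Robust homography (moving -> fixed) from ratio-test matches.

    RANSAC with a 3 px inlier residual over 2000 trials, followed by a
    least-squares refit on the inliers. The default ``model`` constrains
    the fit to a similarity (rotation + isotropic zoom + shift — the
    dominant viewpoint change between the two acquisitions; a full 8-DOF
    projective fit from keypoints concentrated on the vessels is poorly
    conditioned away from them). ``model="projective"`` lifts the
    constraint. Either way the result is returned as a 3x3 homography
    normalized so its last element is 1, with the inlier mask. Fewer than
    4 matches or a degenerate configuration raise
    :class:`RegistrationError`.
    """
    model_cls = {"similarity": SimilarityTransform,
                 "projective": ProjectiveTransform}[model]
    min_samples = {"similarity": 2, "projective": 4}[model]
    xy_a = kp_moving.xy if isinstance(kp_moving, Keypoints) else np.asarray(kp_moving, float)
    xy_b = kp_fixed.xy if isinstance(kp_fixed, Keypoints) else np.asarray(kp_fixed, float)
    if len(matches) < 4:
        raise RegistrationError(f"need >= 4 matches to fit a homography, got {len(matches)}")
    src = xy_a[matches.pairs[:, 0]]
    dst = xy_b[matches.pairs[:, 1]]
    if len(matches) == 4:
        tform = _fit(model_cls, src, dst)
        if tform is None:
            raise RegistrationError("degenerate point configuration")
        inliers = np.ones(4, bool)
    else:
        try:
            tform, inliers = ransac((src, dst), model_cls, min_samples=min_samples,
                                    residual_threshold=residual_threshold,
                                    max_trials=max_trials,
                                    rng=np.random.default_rng(seed))
        except Exception as exc:
            raise RegistrationError(f"RANSAC failed: {exc}") from exc
        if tform is None or inliers is None or inliers.sum() < min_samples:
            raise RegistrationError("RANSAC found no valid model")
        refit = _fit(model_cls, src[inliers], dst[inliers])
        if refit is not None:
            tform = refit
    H = tform.params
    if not np.all(np.isfinite(H)) or abs(H[2, 2]) < 1e-12:
        raise RegistrationError("degenerate homography")
    return H / H[2, 2], inliers


def warp_mask(mask: np.ndarray, H: np.ndarray,
              output_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Warp a binary mask into the fixed frame by H (nearest neighbour)."""
    tform = ProjectiveTransform(matrix=np.asarray(H, float))
    out = warp(np.asarray(mask, float), tform.inverse, order=0, mode="constant",
               cval=0.0, preserve_range=True, output_shape=output_shape)
    return out > 0.5


def registration_success(warped_mask: np.ndarray, fixed_mask: np.ndarray,
                         matches: MatchSet | int) -> tuple[bool, dict]:
    """Accept the registration iff vessel overlap >= 35% and matches >= 10.

    Overlap is the intersection over the smaller of the two vessel areas.
    Empty masks fail with a diagnostic.
    """
    wm = np.asarray(warped_mask, bool)
    fm = np.asarray(fixed_mask, bool)
    if wm.shape != fm.shape:
        raise ValueError("masks must have the same shape")
    n_matches = len(matches) if isinstance(matches, MatchSet) else int(matches)
    a, b = int(wm.sum()), int(fm.sum())
    if a == 0 or b == 0:
        return False, {"overlap": 0.0, "n_matches": n_matches,
                       "error": "empty vessel mask"}
    overlap = float((wm & fm).sum() / min(a, b))
    success = overlap >= OVERLAP_THRESHOLD and n_matches >= MIN_CORRESPONDENCES
    return success, {"overlap": overlap, "n_matches": n_matches}


def fuse_images(moving: np.ndarray, fixed: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Two-color QC overlay: warped moving in green, fixed in magenta.

    Where the two vessel maps coincide the overlay is gray/white; regions
    warped from outside the moving frame render as background.
    """
    fixed = np.asarray(fixed, float)
    tform = ProjectiveTransform(matrix=np.asarray(H, float))
    warped = warp(np.asarray(moving, float), tform.inverse, order=1, mode="constant",
                  cval=0.0, preserve_range=True, output_shape=fixed.shape)

    def _norm(x):
        return x / x.max() if x.max() > 0 else x

    g = _norm(warped)
    m = _norm(fixed)
    return np.stack([m, g, m], axis=-1)


def register_masks(moving_mask: np.ndarray, fixed_mask: np.ndarray,
                   ratio: float = RATIO_THRESHOLD, sigma: float = 2.0,
                   seed: int = 0) -> dict:
    """End-to-end mask registration: SIFT -> ratio test -> RANSAC -> verdict.

    Returns a dict with the homography (or None), keypoint/match counts,
    overlap and the success verdict.
    """
    img_m = vessel_map_for_registration(moving_mask, sigma)
    img_f = vessel_map_for_registration(fixed_mask, sigma)
    kp_m = detect_sift(img_m)
    kp_f = detect_sift(img_f)
    matches = match_ratio_test(kp_m.descriptors, kp_f.descriptors, ratio)
    result = {"n_keypoints_moving": len(kp_m), "n_keypoints_fixed": len(kp_f),
              "n_matches": len(matches), "homography": None, "success": False,
              "overlap": 0.0}
    try:
        H, inliers = estimate_homography(matches, kp_m, kp_f, seed=seed)
    except RegistrationError as exc:
        result["error"] = str(exc)
        return result
    warped = warp_mask(moving_mask, H, output_shape=np.asarray(fixed_mask).shape)
    success, metrics = registration_success(warped, fixed_mask, matches)
    result.update(homography=H, success=success, overlap=metrics["overlap"],
                  n_inliers=int(inliers.sum()), warped_mask=warped)
    return result
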