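"""Synthetic phantom generator: determinism, invariants, ground truth."""

import numpy as np
import pytest

from icgflow.synthetic import (WashInSpec, generate_icg_video,
                               generate_pre_post_pair, generate_seg_dataset,
                               generate_vessel_tree, make_arrival_map,
                               similarity_homography)
from icgflow.segmentation.metrics import dice


class TestVesselTree:
    def test_deterministic_for_seed(self):
        a = generate_vessel_tree(1, (128, 128), 3)
        b = generate_vessel_tree(1, (128, 128), 3)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.recipient_mask, b.recipient_mask)
        assert all(np.array_equal(x, y) for x, y in zip(a.centerlines, b.centerlines))

    def test_seed_sensitivity(self):
        a = generate_vessel_tree(1, (128, 128), 3)
        b = generate_vessel_tree(2, (128, 128), 3)
        assert not np.array_equal(a.mask, b.mask)

    def test_recipient_subset_of_mask(self, tree128):
        assert np.array_equal(tree128.recipient_mask & tree128.mask,
                              tree128.recipient_mask)

    def test_branch_count_and_centerlines_inside(self, tree128):
        assert len(tree128.centerlines) >= 3
        for cl in tree128.centerlines:
            assert tree128.mask[cl[:, 0], cl[:, 1]].all()

    def test_centerlines_eight_connected_and_simple(self, tree128):
        for cl in tree128.centerlines:
            steps = np.abs(np.diff(cl, axis=0)).max(axis=1)
            assert (steps == 1).all()  # 8-connected chain
            assert len(np.unique(cl, axis=0)) == len(cl)  # no self-crossing

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            generate_vessel_tree(1, (32, 32), 1)


class TestWashIn:
    def test_frame_count_arithmetic(self, tree128):
        spec = WashInSpec(make_arrival_map(tree128, "forward"),
                          duration=0.08, fps=25, noise_sd=0)
        video, _ = generate_icg_video(tree128, spec)
        assert video.n_frames == 2

    def test_noiseless_monotone_washin(self, noiseless_forward_video):
        video, _ = noiseless_forward_video
        means = video.frames.reshape(video.n_frames, -1).mean(axis=1)
        assert (np.diff(means) >= 0).all()

    def test_brightness_bounds(self, forward_video):
        video, _ = forward_video
        assert video.frames.dtype == np.uint8
        assert video.frames.min() >= 0 and video.frames.max() <= 255

    def test_background_stays_at_baseline(self, tree128):
        spec = WashInSpec(make_arrival_map(tree128, "forward"), noise_sd=0,
                          baseline=20)
        video, _ = generate_icg_video(tree128, spec)
        bg = video.frames[:, ~tree128.mask]
        assert np.all(bg == 20)

    def test_peak_time_matches_arrival_plus_rise(self, tree128):
        """Per-pixel argmax-brightness time equals arrival + rise within 2 frames."""
        spec = WashInSpec(make_arrival_map(tree128, "forward"), noise_sd=0,
                          rise_time=1.0)
        video, truth = generate_icg_video(tree128, spec)
        rr, cc = np.nonzero(tree128.mask)
        peak_idx = np.argmax(video.frames[:, rr, cc], axis=0)
        t_peak = peak_idx / video.fps
        expected = truth.arrival_map[rr, cc] + spec.rise_time
        assert np.abs(t_peak - expected).max() <= 2 / video.fps

    def test_video_bitwise_deterministic(self, tree128):
        spec = dict(rise_time=1.0, noise_sd=2.0, noise_seed=7)
        arr = make_arrival_map(tree128, "reverse")
        v1, _ = generate_icg_video(tree128, WashInSpec(arr.copy(), **spec))
        v2, _ = generate_icg_video(tree128, WashInSpec(arr.copy(), **spec))
        assert np.array_equal(v1.frames, v2.frames)

    def test_ground_truth_echoes_arrival(self, forward_video, tree128):
        _, truth = forward_video
        arr = make_arrival_map(tree128, "forward")
        assert np.allclose(truth.arrival_map, arr)

    def test_empty_mask_rejected(self, tree128):
        import dataclasses

        empty = dataclasses.replace(tree128,
                                    mask=np.zeros_like(tree128.mask),
                                    recipient_mask=np.zeros_like(tree128.mask),
                                    centerlines=[])
        with pytest.raises(ValueError):
            generate_icg_video(empty, WashInSpec(np.zeros((128, 128))))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WashInSpec(np.zeros((8, 8)), baseline=200, peak_brightness=100)
        with pytest.raises(ValueError):
            WashInSpec(np.full((8, 8), -1.0))


class TestArrivalMap:
    @pytest.mark.parametrize("direction", ["forward", "reverse"])
    def test_monotone_along_centerline(self, tree128, direction):
        arr = make_arrival_map(tree128, direction)
        cl = tree128.centerline
        vals = arr[cl[:, 0], cl[:, 1]]
        diffs = np.diff(vals)
        assert (diffs >= 0).all() if direction == "forward" else (diffs <= 0).all()

    def test_middle_is_v_shaped(self, tree128):
        arr = make_arrival_map(tree128, "middle_to_both_sides")
        cl = tree128.centerline
        vals = arr[cl[:, 0], cl[:, 1]]
        k = int(np.argmin(vals))
        assert 0 < k < len(vals) - 1
        assert (np.diff(vals[:k + 1]) <= 1e-9).all()
        assert (np.diff(vals[k:]) >= -1e-9).all()


class TestPrePostPair:
    def test_identity_transform_gives_identity_homography(self, tree128):
        spec = lambda d, s: WashInSpec(make_arrival_map(tree128, d),  # noqa: E731
                                       direction=d, noise_sd=0, noise_seed=s)
        _, _, truth = generate_pre_post_pair(tree128, spec("forward", 0),
                                             spec("forward", 1), {})
        assert np.allclose(truth.true_homography, np.eye(3))

    def test_warped_pre_mask_reproduces_post_mask(self, tree128):
        from icgflow.registration import warp_mask

        spec = lambda d, s: WashInSpec(make_arrival_map(tree128, d),  # noqa: E731
                                       direction=d, noise_sd=0, noise_seed=s)
        _, _, truth = generate_pre_post_pair(
            tree128, spec("forward", 0), spec("middle_to_both_sides", 1),
            {"rotation": 10, "scale": 1.2, "translation": (5, -3)})
        warped = warp_mask(tree128.mask, truth.true_homography)
        assert dice(warped, truth.mask_post) >= 0.99

    def test_directions_recorded_for_both_videos(self, tree128):
        spec = lambda d: WashInSpec(make_arrival_map(tree128, d), direction=d,  # noqa: E731
                                    noise_sd=0)
        _, _, truth = generate_pre_post_pair(tree128, spec("forward"),
                                             spec("middle_to_both_sides"), {})
        assert truth.true_direction == {"pre": "forward",
                                        "post": "middle_to_both_sides"}

    def test_out_of_frame_transform_rejected(self, tree128):
        spec = WashInSpec(make_arrival_map(tree128, "forward"), noise_sd=0)
        with pytest.raises(ValueError):
            generate_pre_post_pair(tree128, spec, spec,
                                   {"translation": (500, 500)})

    def test_extreme_transform_parameters_rejected(self, tree128):
        spec = WashInSpec(make_arrival_map(tree128, "forward"), noise_sd=0)
        with pytest.raises(ValueError):
            generate_pre_post_pair(tree128, spec, spec, {"rotation": 60})
        with pytest.raises(ValueError):
            generate_pre_post_pair(tree128, spec, spec, {"scale": 3.0})

    def test_homography_normalized(self):
        H = similarity_homography((128, 128), 17, 1.3, (4, 2))
        assert H[2, 2] == pytest.approx(1.0)
        assert abs(np.linalg.det(H)) > 1e-6


def test_seg_dataset_shapes_and_labels():
    samples = generate_seg_dataset(0, 4, (64, 64))
    assert len(samples) == 4
    for s in samples:
        assert s.image.shape == (64, 64) and s.image.dtype == np.uint8
        assert not np.any(s.label_receip & ~s.label_all)
        assert s.label_all.any()
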