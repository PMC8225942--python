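"""Time-luminance curves, delay times and perfusion maps."""

import numpy as np
import pytest

from icgflow.io import ICGVideo
from icgflow.perfusion import (ROI, LuminanceCurve, colorbar_lookup,
                               default_colorbar, delay_time, luminance_curve,
                               perfusion_color_map)
from icgflow.synthetic import (WashInSpec, generate_icg_video,
                               generate_vessel_tree, make_arrival_map)


def _step_video(n_frames=50, shape=(32, 64), fps=25.0):
    """Left half peaks at frame 10, right half exactly 1 s (25 frames) later."""
    frames = np.full((n_frames,) + shape, 20, np.uint8)
    frames[10:, :, :32] = 200
    frames[35:, :, 32:] = 200
    return ICGVideo(frames, fps)


class TestLuminanceCurve:
    def test_constant_video_constant_curve(self):
        video = ICGVideo(np.full((20, 8, 8), 77, np.uint8))
        curve = luminance_curve(video, np.ones((8, 8), bool))
        assert np.all(curve.values == 77)
        assert len(curve.times) == 20

    def test_single_pixel_roi_is_raw_trace(self, forward_video, tree128):
        video, _ = forward_video
        r, c = tree128.centerline[len(tree128.centerline) // 2]
        m = np.zeros(video.frame_shape, bool)
        m[r, c] = True
        curve = luminance_curve(video, m)
        assert np.array_equal(curve.values, video.frames[:, r, c].astype(float))

    def test_matches_generator_curve_noiselessly(self, tree128):
        spec = WashInSpec(make_arrival_map(tree128, "forward"), noise_sd=0)
        video, truth = generate_icg_video(tree128, spec)
        curve = luminance_curve(video, tree128.recipient_mask)
        # reconstruct the expected mean trace from the generator model
        from icgflow.synthetic import _smoothstep

        rr, cc = np.nonzero(tree128.recipient_mask)
        t = video.times[:, None]
        expected = 20 + 180 * _smoothstep(
            (t - truth.arrival_map[rr, cc][None, :]) / spec.rise_time)
        assert np.abs(curve.values - expected.mean(axis=1)).max() < 1.0

    def test_union_mean_is_weighted_mean(self, forward_video):
        video, _ = forward_video
        a = np.zeros(video.frame_shape, bool)
        b = np.zeros(video.frame_shape, bool)
        a[10:20, 10:30] = True
        b[40:45, 50:100] = True
        ca = luminance_curve(video, a).values
        cb = luminance_curve(video, b).values
        cu = luminance_curve(video, a | b).values
        na, nb = a.sum(), b.sum()
        assert np.allclose(cu, (na * ca + nb * cb) / (na + nb))

    def test_empty_roi_rejected(self, forward_video):
        video, _ = forward_video
        with pytest.raises(ValueError):
            luminance_curve(video, np.zeros(video.frame_shape, bool))

    def test_polygon_roi(self, forward_video):
        video, _ = forward_video
        roi = ROI("r1", polygon=[[10, 10], [40, 10], [40, 30], [10, 30]])
        curve = luminance_curve(video, roi)
        assert curve.roi_id == "r1" and len(curve.values) == video.n_frames


class TestDelayTime:
    def test_index_fps_arithmetic(self):
        values = np.zeros(100)
        values[42:] = 10  # unique max first reached at frame 42
        t, flat = delay_time(LuminanceCurve(np.arange(100) / 25.0, values),
                             smooth_width=1)
        assert t == pytest.approx(1.68)
        assert not flat

    def test_tied_maxima_take_earliest(self):
        values = np.zeros(100)
        values[42] = 10
        values[60] = 10
        t, _ = delay_time(LuminanceCurve(np.arange(100) / 25.0, values),
                          smooth_width=1)
        assert t == pytest.approx(1.68)

    def test_flat_curve_flagged(self):
        with pytest.warns(UserWarning):
            t, flat = delay_time(LuminanceCurve(np.arange(10) / 25.0,
                                                np.full(10, 5.0)))
        assert t == 0.0 and flat

    def test_offset_recovery_between_rois(self):
        """Two regions with a 1.0 s generator offset: delay difference 1.0 +- 0.04."""
        video = _step_video()
        left = np.zeros((32, 64), bool)
        left[:, :32] = True
        right = ~left
        t_left, _ = delay_time(luminance_curve(video, left))
        t_right, _ = delay_time(luminance_curve(video, right))
        assert t_right - t_left == pytest.approx(1.0, abs=0.04)


class TestPerfusionMap:
    def test_simultaneous_peak_uniform_color(self):
        frames = np.full((20, 16, 16), 10, np.uint8)
        frames[8:] = 200
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        pmap = perfusion_color_map(ICGVideo(frames), mask)
        colors = pmap.rgb[mask]
        assert np.allclose(colors, colors[0])

    def test_background_black(self, noiseless_forward_video, tree128):
        video, _ = noiseless_forward_video
        pmap = perfusion_color_map(video, tree128.mask)
        assert np.all(pmap.rgb[~tree128.mask] == 0.0)
        assert np.all(pmap.ttp[~tree128.mask] == 0.0)

    def test_map_ttp_equals_pixelwise_delay_time(self, noiseless_forward_video,
                                                 tree128):
        video, _ = noiseless_forward_video
        pmap = perfusion_color_map(video, tree128.mask)
        rr, cc = np.nonzero(tree128.mask)
        for r, c in list(zip(rr, cc))[:: max(1, len(rr) // 20)]:
            curve = LuminanceCurve(video.times, video.frames[:, r, c].astype(float))
            t, _ = delay_time(curve)
            assert pmap.ttp[r, c] == t

    def test_color_ordering_monotone_in_ttp(self, noiseless_forward_video,
                                            tree128):
        from scipy.stats import spearmanr

        video, _ = noiseless_forward_video
        bar = default_colorbar()
        pmap = perfusion_color_map(video, tree128.mask)
        rr, cc = np.nonzero(tree128.mask)
        pos = np.array([colorbar_lookup(pmap.rgb[r, c], bar)[0]
                        for r, c in list(zip(rr, cc))[::37]])
        ttp = pmap.ttp[rr, cc][::37]
        # identical colors for identical times: compare on strictly increasing subset
        rho = spearmanr(ttp, pos).statistic
        assert rho > 0.99

    def test_single_frame_rejected(self, tree128):
        with pytest.raises(ValueError):
            perfusion_color_map(ICGVideo(np.zeros((1, 128, 128), np.uint8)),
                                tree128.mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            perfusion_color_map(ICGVideo(np.zeros((5, 8, 8), np.uint8)),
                                np.zeros((8, 8), bool))


class TestColorbarLookup:
    def test_endpoints(self):
        bar = default_colorbar()
        assert colorbar_lookup(bar[0], bar)[0] == 0.0
        assert colorbar_lookup(bar[-1], bar)[0] == 1.0

    def test_roundtrip_within_resolution(self):
        bar = default_colorbar(64)
        for p in (0.0, 0.25, 0.5, 0.75, 1.0):
            idx = int(round(p * 63))
            back, amb = colorbar_lookup(bar[idx], bar)
            assert back == pytest.approx(p, abs=1 / 64)

    def test_ambiguous_tie_flagged(self):
        bar = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0]], float)
        pos, ambiguous = colorbar_lookup(np.array([1, 0, 0], float), bar)
        assert pos == 0.0 and ambiguous
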