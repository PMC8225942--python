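"""Multi-task segmentation: loss, augmentation, metrics, training sanity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgflow.io import ICGVideo
from icgflow.segmentation import (MultiTaskUNet, SegConfig, SegPrediction,
                                  SegSample, augment_fourfold,
                                  build_multitask_unet, dice, jaccard,
                                  multitask_loss, predict, predict_with_tta,
                                  select_stable_frame, train)
from icgflow.segmentation.train import _softmax2
from icgflow.synthetic import generate_seg_dataset


class TestNetworkContract:
    def test_bottleneck_halving_arithmetic(self):
        # depth 4 halves 64 -> 4; verified through the forward pass shapes
        model = MultiTaskUNet(widths=(2, 2, 2, 2), seed=0)
        x = np.zeros((1, 1, 64, 64), np.float32)
        la, lr = model.forward(x)
        assert la.shape == (1, 2, 64, 64) and lr.shape == (1, 2, 64, 64)

    def test_probabilities_normalized(self, rng):
        model = MultiTaskUNet(widths=(2, 4), seed=0)
        la, _ = model.forward(rng.random((2, 1, 16, 16)).astype(np.float32))
        p = _softmax2(la)
        assert p.min() >= 0 and p.max() <= 1
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_input_rejected_raw(self):
        model = MultiTaskUNet(widths=(2, 2, 2, 2), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 50, 50), np.float32))

    def test_predict_pads_odd_sizes(self):
        model = MultiTaskUNet(widths=(2, 2, 2, 2), seed=0)
        pred = predict(model, np.random.default_rng(0).random((50, 70)))
        assert pred.prob_all.shape == (50, 70)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = MultiTaskUNet(widths=(2, 4), seed=0)
        img = rng.random((16, 16))
        before = predict(model, img).prob_all
        path = model.save(tmp_path / "model")
        back = MultiTaskUNet.load(path)
        assert np.allclose(predict(back, img).prob_all, before)

    def test_build_from_config(self):
        model = build_multitask_unet(SegConfig())
        assert model.depth == 4 and model.widths == (16, 32, 64, 128)


class TestLoss:
    def test_perfect_prediction_zero(self):
        s = SegSample(np.zeros((4, 4)), np.ones((4, 4), bool), np.ones((4, 4), bool))
        p = SegPrediction(np.ones((4, 4)), np.ones((4, 4)))
        assert multitask_loss(p, s) == pytest.approx(0.0, abs=1e-6)

    def test_single_pixel_hand_value(self):
        """p = 0.5 on both heads, alpha = beta = 1 -> 2 ln 2 = 1.3863."""
        s = SegSample(np.zeros((1, 1)), np.ones((1, 1), bool), np.ones((1, 1), bool))
        p = SegPrediction(np.full((1, 1), 0.5), np.full((1, 1), 0.5))
        assert multitask_loss(p, s, 1.0, 1.0) == pytest.approx(1.3863, abs=1e-4)

    def test_alpha_zero_degenerates_to_receip_term(self, rng):
        pa = rng.random((8, 8))
        pr = rng.random((8, 8))
        la = rng.random((8, 8)) > 0.5
        lrec = la & (rng.random((8, 8)) > 0.5)
        s = SegSample(np.zeros((8, 8)), la, lrec)
        p = SegPrediction(pa, pr)
        full = multitask_loss(p, s, 0.0, 2.5)
        only = multitask_loss(SegPrediction(np.full((8, 8), 0.5), pr),
                              SegSample(np.zeros((8, 8)), la, lrec), 0.0, 2.5)
        assert full == pytest.approx(only)

    def test_invariant_to_simultaneous_flip(self, rng):
        pa, pr = rng.random((8, 8)), rng.random((8, 8))
        la = rng.random((8, 8)) > 0.5
        lrec = la & (rng.random((8, 8)) > 0.5)
        base = multitask_loss(SegPrediction(pa, pr),
                              SegSample(np.zeros((8, 8)), la, lrec))
        flipped = multitask_loss(
            SegPrediction(np.fliplr(pa), np.fliplr(pr)),
            SegSample(np.zeros((8, 8)), np.fliplr(la), np.fliplr(lrec)))
        assert base == pytest.approx(flipped)

    def test_zero_probability_clamped(self):
        s = SegSample(np.zeros((2, 2)), np.ones((2, 2), bool), np.ones((2, 2), bool))
        p = SegPrediction(np.zeros((2, 2)), np.ones((2, 2)))
        assert np.isfinite(multitask_loss(p, s))


class TestAugmentation:
    def test_fourfold_count(self):
        samples = generate_seg_dataset(0, 6, (64, 64))
        assert len(augment_fourfold(samples)) == 24

    def test_flips_are_involutions(self):
        from icgflow.segmentation.augment import AUG_VIEWS

        img = np.arange(64, dtype=float).reshape(8, 8)
        for name, view in AUG_VIEWS.items():
            assert np.array_equal(view(view(img)), img), name

    def test_labels_flipped_with_image(self):
        samples = generate_seg_dataset(1, 1, (64, 64))
        out = augment_fourfold(samples)
        horiz = out[1]
        assert np.array_equal(horiz.image, np.fliplr(samples[0].image))
        assert np.array_equal(horiz.label_all, np.fliplr(samples[0].label_all))

    def test_symmetric_image_duplicates_allowed(self):
        sym = SegSample(np.zeros((8, 8)), np.zeros((8, 8), bool),
                        np.zeros((8, 8), bool))
        out = augment_fourfold([sym])
        assert len(out) == 4


class TestMetrics:
    def test_identical_masks(self):
        m = np.eye(8, dtype=bool)
        assert dice(m, m) == 1.0 and jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0 and jaccard(a, b) == 0.0

    def test_half_overlap_hand_values(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100] = True
        b[50:150] = True
        assert dice(a, b) == pytest.approx(0.5)
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_perfect(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) == 1.0 and jaccard(z, z) == 1.0

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            dice(np.full((2, 2), 0.5), np.zeros((2, 2)))

    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    @settings(deadline=None, max_examples=50)
    def test_dice_jaccard_relation(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(20)], bool)
        b = np.array([(bits_b >> i) & 1 for i in range(20)], bool)
        d, j = dice(a, b), jaccard(a, b)
        assert d >= j
        assert d == pytest.approx(2 * j / (1 + j))


class TestTTA:
    def test_constant_model_equals_single_view(self):
        model = MultiTaskUNet(widths=(2, 2), seed=0)
        img = np.full((16, 16), 0.5)
        single = predict(model, img)
        tta = predict_with_tta(model, img)
        assert np.allclose(tta.prob_all, single.prob_all, atol=1e-6)

    def test_probabilities_stay_normalized(self, rng):
        model = MultiTaskUNet(widths=(2, 4), seed=1)
        tta = predict_with_tta(model, rng.random((32, 32)))
        assert tta.prob_all.min() >= 0 and tta.prob_all.max() <= 1


class TestStableFrame:
    def _video(self, means):
        frames = np.tile(np.asarray(means, float)[:, None, None], (1, 8, 8))
        return ICGVideo(frames)

    def test_constant_video_returns_first_frame(self):
        assert select_stable_frame(self._video([50] * 30)) == 0

    def test_plateau_located(self):
        # sigmoid-like rise finishing at frame 60 of 100
        t = np.arange(100)
        means = 20 + 180 * np.clip((t - 10) / 50, 0, 1)
        idx = select_stable_frame(self._video(means))
        assert 50 <= idx <= 65

    def test_generator_plateau(self, noiseless_forward_video, tree128):
        video, truth = noiseless_forward_video
        idx = select_stable_frame(video, tree128.mask)
        t_plateau = truth.time_to_peak[tree128.mask].max()
        assert idx >= 0.9 * t_plateau * video.fps
        assert idx <= video.n_frames - 1

    def test_endless_ramp_warns(self):
        with pytest.warns(UserWarning):
            idx = select_stable_frame(self._video(np.linspace(0, 200, 50)))
        assert idx == 49

    def test_too_short_video_rejected(self):
        with pytest.raises(ValueError):
            select_stable_frame(self._video([1]))


class TestConfig:
    def test_default_learning_rate_schedule(self):
        cfg = SegConfig()
        assert cfg.lr_at(0) == 0.01
        assert cfg.lr_at(20) == 0.001
        assert cfg.lr_at(100) == 0.0001
        assert cfg.total_iterations == 150 and cfg.batch_size == 32

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(alpha=0.0, beta=0.0)

    def test_json_roundtrip(self, tmp_path):
        cfg = SegConfig(alpha=2.0, widths=(4, 8), encoder_depth=2)
        cfg.to_json(tmp_path / "cfg.json")
        back = SegConfig.from_json(tmp_path / "cfg.json")
        assert back == cfg


class TestTraining:
    def test_loss_decreases_and_trace_reproducible(self):
        samples = generate_seg_dataset(3, 8, (64, 64))
        cfg = SegConfig(widths=(2, 4), encoder_depth=2, batch_size=4,
                        total_iterations=30, seed=0)
        _, h1 = train(MultiTaskUNet(cfg.widths, seed=0), samples, cfg)
        _, h2 = train(MultiTaskUNet(cfg.widths, seed=0), samples, cfg)
        assert h1["loss"][-1] < h1["loss"][0]
        assert np.array_equal(h1["loss"], h2["loss"])
        assert h1["lr"][0] == 0.01 and h1["lr"][-1] == 0.001

    def test_single_sample_overfit(self):
        """Memorization oracle: one image reaches Dice >= 0.95 in 150 iterations."""
        sample = generate_seg_dataset(5, 1, (64, 64))[0]
        cfg = SegConfig(batch_size=4, total_iterations=150, seed=0)
        model = MultiTaskUNet(cfg.widths, seed=0)
        model, _ = train(model, [sample, sample], cfg)
        pred = predict(model, sample.image)
        assert dice(pred.mask_all, sample.label_all) >= 0.95

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train(MultiTaskUNet((2, 4), seed=0),
                  generate_seg_dataset(0, 1, (64, 64)), SegConfig(widths=(2, 4),
                  encoder_depth=2))
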