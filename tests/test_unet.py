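"""Segmentation network, augmentation, training loop and quality metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qusbead as q
from qusbead import nn


class _Split:
    def __init__(self, images, masks):
        self.images = images
        self.masks = masks


class TestArchitecture:
    def test_default_config_is_paper_channel_sequence(self):
        cfg = q.UNetConfig()
        assert cfg.block_channels == (64, 128, 256, 512, 1024, 512, 256, 128, 64)
        assert cfg.kernel == 3
        assert cfg.input_size == 256

    def test_asymmetric_channels_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            q.UNetConfig(block_channels=(64, 128, 256, 128, 32))

    def test_even_block_count_rejected(self):
        with pytest.raises(ValueError):
            q.UNetConfig(block_channels=(64, 128, 128, 64))

    def test_forward_shape_and_finiteness(self, tiny_unet_config):
        model = q.build_unet(tiny_unet_config, seed=0)
        x = np.zeros((2, 32, 32, 1), dtype=np.float32)
        logits = model.forward(x, train=False)
        assert logits.shape == (2, 32, 32, 1)
        assert np.all(np.isfinite(logits))
        assert model.n_parameters() > 0

    def test_eval_forward_deterministic(self, tiny_unet_config):
        model = q.build_unet(tiny_unet_config, seed=0)
        x = np.random.default_rng(0).random((1, 32, 32, 1), dtype=np.float32)
        y1 = model.forward(x, train=False)
        y2 = model.forward(x, train=False)
        np.testing.assert_array_equal(y1, y2)

    def test_single_optimization_step_reduces_loss(self, tiny_unet_config):
        model = q.build_unet(tiny_unet_config, seed=1)
        rng = np.random.default_rng(0)
        x = rng.random((2, 32, 32, 1), dtype=np.float32)
        y = (rng.random((2, 32, 32, 1)) > 0.7).astype(np.float32)
        opt = nn.Adam(model.parameters(), lr=1e-2)
        logits = model.forward(x, train=True)
        loss0, grad = nn.bce_with_logits(logits, y)
        model.backward(grad)
        opt.step()
        loss1, _ = nn.bce_with_logits(model.forward(x, train=True), y)
        assert loss1 < loss0


class TestAugment:
    def _pair(self, n=48):
        img = np.random.default_rng(0).random((n, n))
        mask = q.ellipse_mask((n, n), 1.0, 1.0, (n / 2, n / 2), (n / 5, n / 7))
        return img, mask

    def test_identity_params_leave_pair_unchanged(self):
        img, mask = self._pair()
        out_img, out_mask = q.augment(img, mask, q.AugmentParams.identity(), 0)
        np.testing.assert_allclose(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_flip_twice_restores_original(self):
        img, mask = self._pair()
        params = q.AugmentParams(rotation_deg=0, flip_prob=1.0, elastic_alpha=0)
        i1, m1 = q.augment(img, mask, params, 0)
        i2, m2 = q.augment(i1, m1, params, 1)
        np.testing.assert_allclose(i2, img)
        np.testing.assert_array_equal(m2, mask)

    def test_mask_stays_binary_under_full_augmentation(self):
        img, mask = self._pair()
        params = q.AugmentParams(rotation_deg=15, flip_prob=0.5,
                                 elastic_alpha=10, elastic_sigma=4)
        _, out = q.augment(img, mask, params, 3)
        assert set(np.unique(out)) <= {0, 1}

    def test_rotation_preserves_interior_ellipse_area(self):
        mask = q.ellipse_mask((96, 96), 1.0, 1.0, (48.0, 48.0), (18.0, 12.0))
        img = mask.astype(float)
        params = q.AugmentParams(rotation_deg=15, flip_prob=0.0, elastic_alpha=0)
        for seed in range(3):
            _, rotated = q.augment(img, mask, params, seed)
            assert int(rotated.sum()) == pytest.approx(int(mask.sum()), rel=0.02)


class TestTraining:
    def test_fixed_seed_reproducible_history(self, tiny_unet_config):
        rng = np.random.default_rng(5)
        imgs = rng.random((4, 32, 32)).astype(np.float32)
        masks = (rng.random((4, 32, 32)) > 0.8).astype(np.uint8)
        split = _Split(imgs, masks)
        hists = []
        for _ in range(2):
            model = q.build_unet(tiny_unet_config, seed=2)
            hists.append(q.train(model, split, split,
                                 q.TrainConfig(epochs=2, batch_size=2, seed=3)))
        assert hists[0] == hists[1]

    def test_divergence_aborts_with_diagnostic(self, tiny_unet_config):
        rng = np.random.default_rng(0)
        imgs = rng.random((2, 32, 32)).astype(np.float32)
        masks = (rng.random((2, 32, 32)) > 0.5).astype(np.uint8)
        split = _Split(imgs, masks)
        model = q.build_unet(tiny_unet_config, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            q.train(model, split, split,
                    q.TrainConfig(epochs=3, batch_size=2, learning_rate=1e12, seed=0))

    def test_empty_sets_rejected(self, tiny_unet_config):
        model = q.build_unet(tiny_unet_config, seed=0)
        empty = _Split(np.empty((0, 32, 32)), np.empty((0, 32, 32)))
        with pytest.raises(ValueError):
            q.train(model, empty, empty, q.TrainConfig(epochs=1))


class TestPredict:
    def test_threshold_monotonicity(self, tiny_unet_config):
        model = q.build_unet(tiny_unet_config, seed=0)
        img = np.random.default_rng(0).random((32, 32))
        areas = [q.predict_mask(model, img, threshold=t).sum()
                 for t in (0.3, 0.5, 0.7)]
        assert areas[0] >= areas[1] >= areas[2]

    def test_extreme_logits_give_constant_masks(self, tiny_unet_config):
        model = q.build_unet(tiny_unet_config, seed=0)
        # drive the head bias to extremes so the sigmoid saturates
        img = np.random.default_rng(0).random((32, 32))
        model.head.b[...] = 100.0
        model.head.W[...] = 0.0
        assert q.predict_mask(model, img).all()
        model.head.b[...] = -100.0
        assert not q.predict_mask(model, img).any()


class TestConfusionAndMetrics:
    def test_perfect_prediction(self):
        ones = np.ones((10, 10), dtype=np.uint8)
        c = q.confusion(ones, ones)
        assert (c.tp, c.tn, c.fp, c.fn) == (100, 0, 0, 0)

    def test_complement_prediction(self):
        rng = np.random.default_rng(0)
        gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = q.confusion(1 - gt, gt)
        assert c.tp == 0 and c.tn == 0

    def test_counts_match_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pred = (rng.random((4, 4)) > 0.5).astype(np.uint8)
            gt = (rng.random((4, 4)) > 0.5).astype(np.uint8)
            c = q.confusion(pred, gt)
            tp = tn = fp = fn = 0
            for i in range(4):
                for j in range(4):
                    if pred[i, j] and gt[i, j]:
                        tp += 1
                    elif pred[i, j] and not gt[i, j]:
                        fp += 1
                    elif not pred[i, j] and gt[i, j]:
                        fn += 1
                    else:
                        tn += 1
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            q.confusion(np.full((3, 3), 2), np.zeros((3, 3), dtype=int))

    def test_worked_example(self):
        m = q.metrics(q.ConfusionCounts(tp=6, fp=2, fn=2, tn=90))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.dice == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.96)

    def test_identical_masks_dice_one_disjoint_zero(self):
        assert q.metrics(q.ConfusionCounts(5, 5, 0, 0)).dice == 1.0
        assert q.metrics(q.ConfusionCounts(0, 0, 5, 5)).dice == 0.0

    def test_both_empty_convention(self):
        m = q.metrics(q.ConfusionCounts(tp=0, tn=16, fp=0, fn=0))
        assert m.dice == m.precision == m.recall == 1.0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_dice_equals_f1_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        b = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        m_ab = q.metrics(q.confusion(a, b))
        # F1 = harmonic mean of precision and recall
        if m_ab.precision + m_ab.recall > 0:
            f1 = 2 * m_ab.precision * m_ab.recall / (m_ab.precision + m_ab.recall)
            assert m_ab.dice == pytest.approx(f1)
        assert m_ab.f1 == m_ab.dice
        m_ba = q.metrics(q.confusion(b, a))
        assert m_ab.dice == pytest.approx(m_ba.dice)
        for v in (m_ab.accuracy, m_ab.precision, m_ab.recall, m_ab.dice):
            assert 0.0 <= v <= 1.0


class TestAreaRatio:
    def test_empty_and_half_filled(self):
        assert q.area_ratio(np.zeros((10, 10), dtype=np.uint8)) == 0.0
        half = np.zeros((10, 10), dtype=np.uint8)
        half[:5] = 1
        assert q.area_ratio(half) == 0.5

    def test_ellipse_matches_analytic_area(self):
        h, w = 512, 512
        az, ax = 60.0, 40.0
        mask = q.ellipse_mask((h, w), 1.0, 1.0, (256.0, 256.0), (az, ax))
        expected = np.pi * az * ax / (h * w)
        assert q.area_ratio(mask) == pytest.approx(expected, rel=0.02)

    def test_flagging_window(self):
        assert q.flag_area_ratio(0.03)
        assert not q.flag_area_ratio(0.1)
        assert q.flag_area_ratio(0.2)


class TestKFold:
    def test_groups_never_split_across_folds(self):
        groups = np.repeat(np.arange(12), 5)
        for trn, tst in q.kfold_by_group(groups, n_folds=4, seed=0):
            assert set(groups[trn]).isdisjoint(set(groups[tst]))
            assert len(trn) + len(tst) == len(groups)

    def test_every_index_tested_exactly_once(self):
        groups = np.repeat(np.arange(8), 3)
        tested = np.concatenate([tst for _, tst in q.kfold_by_group(groups, 4, 1)])
        assert sorted(tested) == list(range(len(groups)))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, tiny_unet_config):
        model = q.build_unet(tiny_unet_config, seed=4)
        x = np.random.default_rng(0).random((1, 32, 32, 1), dtype=np.float32)
        y0 = model.forward(x, train=False)
        q.save_checkpoint(model, tmp_path / "model.npz", q.TrainConfig())
        restored = q.load_checkpoint(tmp_path / "model.npz")
        np.testing.assert_allclose(restored.forward(x, train=False), y0, atol=1e-7)
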