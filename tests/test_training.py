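"""Loss function, augmentation, splitting and early-stopping behaviour."""

import math

import numpy as np
import pytest

from murivess import training as tr
from murivess.nn import unet

TINY = unet.UNetConfig(base_filters=2, bottleneck_filters=4, decoder_filters=2)


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy_spot_value(self):
        loss = tr.focal_loss(np.array([0.5]), np.array([1.0]), gamma=0)
        assert loss == pytest.approx(-math.log(0.5), abs=1e-6)

    def test_gamma_zero_equals_bce_on_random_tensors(self, rng):
        p = rng.uniform(0.01, 0.99, (5, 5, 5))
        y = (rng.random((5, 5, 5)) < 0.3).astype(float)
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert tr.focal_loss(p, y, gamma=0) == pytest.approx(bce, abs=1e-9)

    def test_closed_form_spot_value_gamma_two(self):
        # y=1, p=0.9: (1-p)^2 * (-ln p) = 0.01 * 0.105361 = 0.00105361
        loss = tr.focal_loss(np.array([0.9]), np.array([1.0]), gamma=2)
        assert loss == pytest.approx(0.1**2 * -math.log(0.9), abs=1e-8)

    def test_perfect_prediction_is_epsilon_bounded(self):
        p = np.array([1.0, 0.0])
        y = np.array([1.0, 0.0])
        assert tr.focal_loss(p, y, gamma=2) < 1e-10

    def test_nonnegative_and_monotone_toward_target(self):
        grid = np.linspace(0.05, 0.95, 19)
        losses_y1 = [tr.focal_loss(np.array([p]), np.array([1.0]), 2) for p in grid]
        losses_y0 = [tr.focal_loss(np.array([p]), np.array([0.0]), 2) for p in grid]
        assert all(l >= 0 for l in losses_y1 + losses_y0)
        assert all(a > b for a, b in zip(losses_y1[:-1], losses_y1[1:]))
        assert all(a < b for a, b in zip(losses_y0[:-1], losses_y0[1:]))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            tr.focal_loss(np.array([0.5]), np.array([1.0]), gamma=-1)

    def test_gradient_matches_numerical(self, rng):
        p = rng.uniform(0.1, 0.9, 64)
        y = (rng.random(64) < 0.5).astype(float)
        g = tr.focal_loss_grad(p, y, 2.0)
        eps = 1e-6
        for i in (0, 13, 40):
            up, down = p.copy(), p.copy()
            up[i] += eps
            down[i] -= eps
            numeric = (tr.focal_loss(up, y, 2.0) - tr.focal_loss(down, y, 2.0)) / (2 * eps)
            assert g[i] == pytest.approx(numeric, rel=1e-4)


class TestAugment:
    def test_flip_is_involution_and_label_binary(self, rng):
        img = rng.random((8, 8, 8)).astype(np.float32)
        lab = (rng.random((8, 8, 8)) < 0.1).astype(np.float32)
        # force the flip branch deterministically, twice with the same axis
        cfg = tr.AugmentConfig(brightness_sigma=0, noise_sigma=0, prob=1.0)
        r1 = np.random.default_rng(0)
        a_img, a_lab = tr.augment(img, lab, cfg, r1)
        r2 = np.random.default_rng(0)
        b_img, b_lab = tr.augment(a_img, a_lab, cfg, r2)
        assert np.allclose(b_img, np.clip(img, 0, 1))
        assert np.array_equal(b_lab, lab)
        assert set(np.unique(a_lab)) <= {0.0, 1.0}

    def test_seeded_augmentation_reproducible(self, rng):
        img = rng.random((8, 8, 8)).astype(np.float32)
        lab = np.zeros_like(img)
        cfg = tr.AugmentConfig()
        a = tr.augment(img, lab, cfg, np.random.default_rng(5))
        b = tr.augment(img, lab, cfg, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0])

    def test_intensity_jitter_leaves_label_untouched(self, rng):
        img = rng.random((6, 6, 6)).astype(np.float32)
        lab = (rng.random((6, 6, 6)) < 0.2).astype(np.float32)
        out_img, out_lab = tr.augment(img, lab, tr.AugmentConfig(prob=1.0), np.random.default_rng(1))
        assert np.array_equal(np.unique(out_lab), np.unique(lab))
        assert out_img.min() >= 0 and out_img.max() <= 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tr.augment(np.zeros((4, 4, 4)), np.zeros((4, 4, 2)), tr.AugmentConfig(), np.random.default_rng(0))


class TestSplitPatches:
    def test_ten_patches_split_eight_two(self):
        train, val = tr.split_patches(list(range(10)), 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_union_is_input_multiset_and_seed_reproducible(self):
        items = list(range(23))
        t1, v1 = tr.split_patches(items, 0.8, seed=3)
        t2, v2 = tr.split_patches(items, 0.8, seed=3)
        assert t1 == t2 and v1 == v2
        assert sorted(t1 + v1) == items
        t3, _ = tr.split_patches(items, 0.8, seed=4)
        assert t3 != t1

    def test_too_few_patches_rejected(self):
        with pytest.raises(ValueError):
            tr.split_patches([1, 2, 3], 0.8, seed=0)


class TestEarlyStopping:
    def test_plateau_after_improvement_stops_at_epoch_five(self):
        losses = [1.0, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9]
        assert tr.early_stopping_epoch(losses, patience=3, min_delta=1e-4) == 5

    def test_monotone_improvement_runs_all_epochs(self):
        losses = [1.0 - 0.01 * i for i in range(50)]
        assert tr.early_stopping_epoch(losses, patience=30, min_delta=1e-4) == 50

    def test_sub_min_delta_improvement_counts_as_plateau(self):
        losses = [1.0] + [1.0 - 1e-5 * i for i in range(1, 10)]
        assert tr.early_stopping_epoch(losses, patience=4, min_delta=1e-4) == 5

    def test_recovery_resets_patience(self):
        losses = [1.0, 0.9, 0.9, 0.9, 0.7, 0.7, 0.7, 0.7]
        assert tr.early_stopping_epoch(losses, patience=4, min_delta=1e-4) == 8

    def test_reference_setting_long_plateau(self):
        losses = [0.5] + [0.5] * 30
        assert tr.early_stopping_epoch(losses, patience=30, min_delta=1e-4) == 31


class TestTrainModel:
    def _easy_patches(self, n, rng):
        # dark blob on bright background in tiny 8^3 patches
        out = []
        for _ in range(n):
            img = np.full((8, 8, 8), 0.8, dtype=np.float32) + rng.normal(0, 0.02, (8, 8, 8)).astype(np.float32)
            lab = np.zeros((8, 8, 8), dtype=np.float32)
            z, y, x = rng.integers(2, 6, 3)
            lab[z - 1 : z + 1, y - 1 : y + 1, x - 1 : x + 1] = 1
            img[lab == 1] = 0.1
            out.append((np.clip(img, 0, 1), lab))
        return out

    def test_loss_decreases_on_easy_task(self, rng):
        patches = self._easy_patches(12, rng)
        model = unet.build_unet(TINY, seed=0)
        cfg = tr.TrainConfig(max_epochs=5, patience=5, batch_size=4, learning_rate=3e-3, seed=0)
        model, hist = tr.train_model(model, patches[:9], patches[9:], cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_never_exceeds_max_epochs_and_restores_best(self, rng):
        patches = self._easy_patches(8, rng)
        model = unet.build_unet(TINY, seed=1)
        cfg = tr.TrainConfig(max_epochs=3, patience=3, batch_size=4, seed=0)
        model, hist = tr.train_model(model, patches[:6], patches[6:], cfg)
        assert len(hist) <= 3

    def test_empty_sets_rejected(self):
        model = unet.build_unet(TINY, seed=0)
        with pytest.raises(ValueError):
            tr.train_model(model, [], [], tr.TrainConfig())


class TestConfigValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            tr.TrainConfig(split_ratio=1.2)
        with pytest.raises(ValueError):
            tr.TrainConfig(gamma=-0.5)
        with pytest.raises(ValueError):
            tr.TrainConfig(patience=200, max_epochs=100)
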