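import numpy as np
import pytest

from lcseg.unet import (UNet3D, UNetSegmenter, dice_loss, learning_rate,
                        sliding_window_predict, window_coverage_counts)


class TestDiceLoss:
    def test_perfect_overlap(self, rng):
        t = (rng.random((6, 6, 6)) > 0.7).astype(float)
        assert dice_loss(t, t, smooth=1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((4, 4, 4)); b[3, 3, 3] = 1
        assert dice_loss(a, b, smooth=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_double_volume_prediction(self):
        # Prediction covers the target plus an equal extra volume:
        # Dice = 2|T| / (2|T| + |T|) = 2/3, loss = 1/3.
        t = np.zeros((5, 5, 5)); t.reshape(-1)[:10] = 1
        p = np.zeros((5, 5, 5)); p.reshape(-1)[:20] = 1
        assert dice_loss(p, t, smooth=1e-12) == pytest.approx(1 / 3,
                                                              abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))


class TestLearningRateSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (1, 0.002), (6, 1e-4), (11, 5e-6), (16, 2.5e-7),
    ])
    def test_95_percent_drop_every_five_epochs(self, epoch, expected):
        assert learning_rate(epoch) == pytest.approx(expected, rel=1e-12)

    def test_constant_within_a_block(self):
        assert learning_rate(5) == learning_rate(1)
        assert learning_rate(10) == learning_rate(6)


class TestSlidingWindow:
    def test_non_overlapping_stride_equals_tiling(self, rng):
        data = rng.random((1, 8, 8, 8)).astype(np.float32)

        def fn(p):
            return p[0] * 2.0

        out = sliding_window_predict(fn, data, patch=4, stride=4)
        assert np.allclose(out, data[0] * 2.0)

    def test_constant_model_any_stride(self, rng):
        data = rng.random((1, 10, 12, 8)).astype(np.float32)

        def fn(p):
            return np.full(p.shape[1:], 0.7)

        out = sliding_window_predict(fn, data, patch=4, stride=3)
        assert np.allclose(out, 0.7)

    def test_coverage_counts_match_brute_force_enumeration(self):
        shape = (14, 11, 9)
        patch, stride = 4, 3
        counts = window_coverage_counts(shape, patch, stride)

        # Brute-force oracle: enumerate all windows per voxel.
        def origins(n):
            out = list(range(0, n - patch + 1, stride))
            if out[-1] != n - patch:
                out.append(n - patch)
            return out

        ref = np.zeros(shape, dtype=int)
        for v in np.ndindex(shape):
            c = 0
            for z in origins(shape[0]):
                for y in origins(shape[1]):
                    for x in origins(shape[2]):
                        if (z <= v[0] < z + patch and y <= v[1] < y + patch
                                and x <= v[2] < x + patch):
                            c += 1
            ref[v] = c
        assert np.array_equal(counts, ref)

    def test_spy_model_sees_expected_origin_count(self, rng):
        data = rng.random((1, 9, 9, 9)).astype(np.float32)
        calls = []

        def spy(p):
            calls.append(p.shape)
            return np.zeros(p.shape[1:])

        sliding_window_predict(spy, data, patch=4, stride=4)
        # origins per axis: 0, 4, 5 (final flush window) -> 27 windows
        assert len(calls) == 27

    def test_volume_smaller_than_patch_padded_and_cropped(self):
        data = np.ones((1, 6, 6, 6), dtype=np.float32)

        def fn(p):
            return p[0]

        out = sliding_window_predict(fn, data, patch=8, stride=8)
        assert out.shape == (6, 6, 6)
        assert np.allclose(out, 1.0)

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            sliding_window_predict(lambda p: p[0], np.ones((1, 4, 4, 4)),
                                   patch=2, stride=0)


class TestNetworkMechanics:
    def test_forward_output_in_unit_interval(self, rng):
        net = UNet3D(in_channels=2, base_filters=4, depth=2, seed=1)
        x = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
        out = net.forward(x)
        assert out.shape == (8, 8, 8)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_initialization_is_seed_deterministic(self, rng):
        a = UNet3D(1, base_filters=4, seed=7)
        b = UNet3D(1, base_filters=4, seed=7)
        for (pa, _), (pb, _) in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)
        c = UNet3D(1, base_filters=4, seed=8)
        assert not all(
            np.array_equal(pa, pc)
            for (pa, _), (pc, _) in zip(a.params(), c.params()))

    def test_end_to_end_gradient_matches_finite_differences(self):
        from lcseg._nn import generalized_dice_loss_grad

        rng = np.random.default_rng(3)
        net = UNet3D(1, base_filters=2, depth=1, seed=3)
        x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
        t = (rng.random((4, 4, 4)) < 0.3).astype(np.float32)

        pred = net.forward(x)
        _, grad = generalized_dice_loss_grad(pred, t)
        net.backward(grad)
        # Check the largest-gradient weight of the first conv against
        # central differences (the largest entry keeps the check above
        # the float32 finite-difference noise floor).
        conv = net.enc[0].layers[0]
        idx = tuple(np.unravel_index(np.argmax(np.abs(conv.dW)),
                                     conv.dW.shape))
        analytic = float(conv.dW[idx])
        eps = 1e-3
        w0 = conv.W[idx]
        conv.W[idx] = w0 + eps
        lp, _ = generalized_dice_loss_grad(net.forward(x), t)
        conv.W[idx] = w0 - eps
        lm, _ = generalized_dice_loss_grad(net.forward(x), t)
        conv.W[idx] = w0
        assert analytic == pytest.approx((lp - lm) / (2 * eps), rel=0.1,
                                         abs=1e-6)


TINY = dict(base_filters=4, patch_size=16, stride=8, epochs=2, batch_size=2,
            steps_per_epoch=3, seed=11)


class TestTraining:
    def test_same_seed_reproduces_loss_trace(self, cohort6):
        a = UNetSegmenter(side="left", variant="image", **TINY)
        b = UNetSegmenter(side="left", variant="image", **TINY)
        a.fit(cohort6[:3])
        b.fit(cohort6[:3])
        assert a.loss_trace_ == b.loss_trace_

    def test_too_few_cases_rejected(self, cohort6):
        with pytest.raises(ValueError):
            UNetSegmenter(**TINY).fit(cohort6[:1])

    def test_patch_not_divisible_rejected(self, cohort6):
        est = UNetSegmenter(side="left", patch_size=18, depth=2)
        with pytest.raises(ValueError):
            est.fit(cohort6[:3])

    def test_unknown_variant_rejected(self, cohort6):
        est = UNetSegmenter(side="left", variant="bogus", **TINY)
        with pytest.raises(ValueError):
            est.fit(cohort6[:3])

    def test_two_channel_variant_trains_and_predicts(self, cohort6):
        est = UNetSegmenter(side="left", variant="image+phase", **TINY)
        est.fit(cohort6[:3])
        assert est.n_channels_ == 2
        soft = est.predict(cohort6[3].image)
        assert soft.shape == cohort6[3].image.shape
        assert soft.data.min() >= 0 and soft.data.max() <= 1

    def test_loss_decreases_with_training(self, cohort6):
        # Learning sanity at desk scale: the mean objective of the last
        # epoch improves on the first.
        est = UNetSegmenter(side="left", variant="nmz", base_filters=6,
                            patch_size=16, stride=8, epochs=5, batch_size=2,
                            steps_per_epoch=8, seed=5)
        est.fit(cohort6[:4])
        assert est.loss_trace_[-1] < est.loss_trace_[0]
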