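"""Gradient-based BTR: loss, routed gradients, AdamW, clamp/recenter, training."""

import numpy as np
import pytest

import blindtip as bt
from blindtip.diffbtr import LossParams, OptimizerState

from conftest import random_instance


class TestOpeningMSE:
    def test_generating_tip_zero_on_noise_free(self, tiny_dataset):
        assert bt.opening_mse(tiny_dataset.frames, tiny_dataset.truth.tip) < 1e-25

    def test_delta_tip_zero_anywhere(self, rng):
        frames = [bt.HeightImage(rng.normal(size=(6, 6))) for _ in range(3)]
        assert bt.opening_mse(frames, bt.InvertedTip([[0.0]])) == 0.0

    def test_blunt_pillar_worked_example(self):
        # opening of [0,2,0] with a width-3 pillar is flat zero: MSE = 4/3
        mse = bt.opening_mse([bt.HeightImage([[0, 2, 0]])], bt.InvertedTip(np.zeros((1, 3))))
        assert mse == pytest.approx(4.0 / 3.0)

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            bt.opening_mse([], bt.InvertedTip([[0.0]]))


class TestMSEGradient:
    def test_zero_at_perfect_tip(self, tiny_dataset):
        g = bt.mse_gradient(tiny_dataset.frames[0], tiny_dataset.truth.tip)
        np.testing.assert_array_equal(g, 0.0)

    def test_matches_finite_differences(self, rng):
        # tie-free random instances; central differences with small h
        h = 1e-6
        for _ in range(8):
            img, tip = random_instance(rng, im_shape=(6, 6), tip_shape=(3, 3))
            # keep every pixel strictly below 0 so the +-h probes stay in the
            # admissible region (no clamp kink inside the difference stencil)
            tip = bt.InvertedTip(tip.p - 0.1, tip.pixel_size, tip.origin_index)
            g = bt.mse_gradient(img, tip)
            fd = np.zeros_like(tip.p)
            for k in range(tip.p.size):
                pp, pm = tip.p.copy(), tip.p.copy()
                pp.flat[k] += h
                pm.flat[k] -= h
                fd.flat[k] = (
                    bt.opening_mse([img], bt.InvertedTip(pp))
                    - bt.opening_mse([img], bt.InvertedTip(pm))
                ) / (2 * h)
            np.testing.assert_allclose(g, fd, atol=1e-6)

    def test_routing_cancellation_on_flat_image(self):
        # argmax and argmin land on the same tip pixel: contributions cancel
        img = bt.HeightImage(np.full((5, 5), 2.0))
        tip = bt.InvertedTip([[-1.0, 0.0, -1.0]])
        np.testing.assert_array_equal(bt.mse_gradient(img, tip), 0.0)


class TestAdamW:
    def test_zero_gradient_no_reg_is_identity(self, truth_tip):
        state = OptimizerState.zeros(truth_tip.shape)
        out, _ = bt.adamw_step(truth_tip, np.zeros(truth_tip.shape), state, LossParams(lam=0.0))
        np.testing.assert_array_equal(out.p, truth_tip.p)

    def test_pure_decay_shrinks_toward_pillar(self, truth_tip):
        params = LossParams(lam=0.05)
        tip = truth_tip
        state = OptimizerState.zeros(tip.shape)
        norms = [np.sum(tip.p**2)]
        for _ in range(5):
            tip, state = bt.adamw_step(tip, np.zeros(tip.shape), state, params)
            norms.append(np.sum(tip.p**2))
        assert all(b < a for a, b in zip(norms, norms[1:]))
        # closed form: each step multiplies p by (1 - 2*lam*lr)
        factor = (1.0 - 2 * params.lam * params.lr) ** 5
        np.testing.assert_allclose(tip.p, truth_tip.p * factor, rtol=1e-12)

    def test_first_step_is_lr_times_sign(self):
        tip = bt.InvertedTip(np.zeros((2, 2)))
        grad = np.array([[0.3, 1.7], [0.01, 5.0]])  # positive: pushes p downward
        params = LossParams(lam=0.0)
        out, state = bt.adamw_step(tip, grad, OptimizerState.zeros((2, 2)), params)
        np.testing.assert_allclose(out.p, -params.lr, rtol=1e-6)
        assert state.step == 1


class TestClampRecenter:
    def test_centered_nonpositive_unchanged(self, truth_tip):
        out = bt.clamp_and_recenter(truth_tip)
        np.testing.assert_array_equal(out.p, truth_tip.p)

    def test_shifted_peak_moved_back(self):
        p = np.full((7, 7), -4.0)
        p[5, 3] = 0.0
        p[4:7, 2:5] = np.maximum(p[4:7, 2:5], -1.0)
        p[5, 3] = 0.0
        out = bt.clamp_and_recenter(bt.InvertedTip(p))
        # the weighted center of the blob was at row 5; origin row is 3
        assert out.p[3, 3] == 0.0
        # vacated bottom rows filled with the minimum
        np.testing.assert_array_equal(out.p[6], -4.0)

    def test_positive_values_clamped(self):
        tip = bt.InvertedTip(np.zeros((3, 3)))
        tip.p += 0.0
        raw = tip.p.copy()
        raw[0, 0] = 0.0
        out = bt.clamp_and_recenter(tip)
        assert out.p.max() <= 0.0

    def test_all_equal_tip_no_shift(self):
        tip = bt.InvertedTip(np.full((4, 4), -2.0))
        out = bt.clamp_and_recenter(tip)
        np.testing.assert_array_equal(out.p, tip.p)


class TestTraining:
    def test_invariants_every_epoch_and_loss_decreases(self, tiny_dataset):
        res = bt.DifferentiableBTR(tiny_dataset, (5, 5)).fit(lam=0.0, epochs=60)
        h = res.history
        assert len(h.mse) == 60
        assert max(h.max_p) <= 0.0
        # the integer shift brings the centroid within half a pixel of the
        # origin; weights lost off the grid edge can add a small excess
        assert max(h.centroid_distance) <= 0.75
        assert h.mse[-1] < h.mse[0]

    def test_noise_free_training_drives_mse_small(self, tiny_dataset):
        res = bt.DifferentiableBTR(tiny_dataset, (5, 5)).fit(lam=0.0, epochs=400)
        assert res.history.mse[-1] < 1e-4

    def test_large_lambda_drives_blunt_pillar(self, tiny_dataset):
        res = bt.DifferentiableBTR(tiny_dataset, (5, 5)).fit(lam=10.0, epochs=50)
        # the penalty dominates: the tip stays within noise of the flat pillar
        assert np.all(res.tip.p > -0.5)

    def test_lambda_monotone_tip_norm(self, tiny_noisy_dataset):
        norms = []
        for lam in (1e-6, 1e-2, 1.0):
            res = bt.DifferentiableBTR(tiny_noisy_dataset, (5, 5)).fit(lam=lam, epochs=150)
            norms.append(float(np.sum(res.tip.p**2)))
        assert norms[0] >= norms[1] >= norms[2]

    def test_epochs_validation(self, tiny_dataset):
        with pytest.raises(ValueError):
            bt.DifferentiableBTR(tiny_dataset, (5, 5)).fit(epochs=0)

    def test_history_frame_and_summary(self, tiny_dataset):
        res = bt.DifferentiableBTR(tiny_dataset, (5, 5)).fit(lam=1e-5, epochs=5)
        df = res.history.to_frame()
        assert list(df.columns[:3]) == ["epoch", "mse", "regularization"]
        assert len(df) == 5
        assert "lambda" in res.summary()

    def test_train_tip_functional_wrapper(self, tiny_dataset):
        tip, history = bt.train_tip(tiny_dataset, bt.LossParams(lam=0.0, epochs=5), (5, 5))
        assert tip.shape == (5, 5)
        assert len(history.mse) == 5
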