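"""Loss components: closed-form values, reductions, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.metrics import structural_similarity

from accelt2 import (PRESETS, LossWeights, RandomConvFeatures, SigmoidParams,
                     feature_loss, l1_scaled, l1_scaled_roi, network_loss,
                     sigmoid_scale, ssim_loss)
from accelt2.nn import Tensor

KNEE = PRESETS["knee"].sigmoid


class TestSigmoidScale:
    def test_knee_midpoint(self):
        # midpoint of the transition: y_l + (y_h - y_l)/2 = 0.55
        assert sigmoid_scale(50.0, KNEE) == pytest.approx(0.55, abs=1e-12)

    def test_knee_upper_limit_value(self):
        expected = 0.1 + 0.9 / (1 + np.exp(-5.0))
        assert sigmoid_scale(100.0, KNEE) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_and_open_range(self, rng):
        xs = np.sort(rng.uniform(-50, 250, 200))
        ys = sigmoid_scale(xs, KNEE)
        assert (np.diff(ys) > 0).all()
        assert (ys > KNEE.y_l).all() and (ys < KNEE.y_h).all()

    def test_tensor_and_numpy_paths_agree(self, rng):
        x = rng.uniform(0, 120, (5, 5))
        tn = sigmoid_scale(Tensor(x), KNEE)
        np.testing.assert_allclose(tn.data, sigmoid_scale(x, KNEE),
                                   rtol=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(x=st.floats(-100, 250), delta=st.floats(0.01, 100))
    def test_order_preservation_property(self, x, delta):
        # strictly increasing wherever float64 still resolves the tail
        assert sigmoid_scale(x, KNEE) < sigmoid_scale(x + delta, KNEE)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(100.0, 0.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            SigmoidParams(0.0, 100.0, 0.0, 1.0)


class TestL1Scaled:
    def test_identity_zero(self, rng):
        t = rng.uniform(20, 60, (6, 6))
        assert l1_scaled(t, t, KNEE) == 0.0

    def test_two_pixel_hand_value(self):
        t = np.array([[40.0, 80.0]])
        p = np.array([[50.0, 80.0]])
        expected = abs(sigmoid_scale(40.0, KNEE) -
                       sigmoid_scale(50.0, KNEE)) / 2.0
        assert l1_scaled(t, p, KNEE) == pytest.approx(expected, rel=1e-12)

    def test_roi_equals_global_when_roi_is_everything(self, rng):
        t = rng.uniform(20, 60, (6, 6))
        p = t + rng.normal(0, 5, (6, 6))
        roi = np.ones((6, 6), bool)
        assert l1_scaled_roi(t, p, roi, KNEE) == pytest.approx(
            l1_scaled(t, p, KNEE), rel=1e-12)

    def test_empty_roi_raises(self, rng):
        t = rng.uniform(20, 60, (4, 4))
        with pytest.raises(ValueError, match="ROI"):
            l1_scaled_roi(t, t, np.zeros((4, 4), bool), KNEE)

    def test_tensor_path_matches_numpy(self, rng):
        t = rng.uniform(20, 60, (5, 5))
        p = t + rng.normal(0, 3, (5, 5))
        roi = rng.random((5, 5)) < 0.5
        lt = l1_scaled_roi(t, Tensor(p), roi, KNEE)
        assert float(lt.data) == pytest.approx(
            l1_scaled_roi(t, p, roi, KNEE), rel=1e-10)


class TestSsimLoss:
    def test_identity_zero(self, rng):
        t = rng.uniform(20, 60, (16, 16))
        assert ssim_loss(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_flat_vs_structured_near_one(self, rng):
        t = rng.uniform(0, 150, (32, 32))
        p = np.zeros((32, 32))
        assert ssim_loss(t, p, data_range=150.0) > 0.85

    def test_symmetry(self, rng):
        a = rng.uniform(20, 60, (16, 16))
        b = a + rng.normal(0, 4, (16, 16))
        assert ssim_loss(a, b) == pytest.approx(ssim_loss(b, a), rel=1e-10)

    def test_matches_skimage(self, rng):
        a = rng.uniform(0, 150, (24, 24))
        b = np.clip(a + rng.normal(0, 10, (24, 24)), 0, 150)
        ours = 1.0 - ssim_loss(a, b, data_range=150.0)
        ref = structural_similarity(a / 150.0, b / 150.0, win_size=7,
                                    data_range=1.0)
        assert ours == pytest.approx(ref, rel=1e-7)


class TestFeatureLoss:
    extractor = RandomConvFeatures(seed=0)

    def test_identity_zero(self, rng):
        t = rng.uniform(20, 60, (16, 16))
        assert feature_loss(t, t, self.extractor) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_seeded_fallback_reproducible(self, rng):
        t = rng.uniform(20, 60, (16, 16))
        p = t + rng.normal(0, 5, (16, 16))
        a = feature_loss(t, p, RandomConvFeatures(seed=3))
        b = feature_loss(t, p, RandomConvFeatures(seed=3))
        assert a == b

    def test_nonnegative(self, rng):
        t = rng.uniform(20, 60, (16, 16))
        p = rng.uniform(20, 60, (16, 16))
        assert feature_loss(t, p, self.extractor) >= 0

    def test_missing_extractor_raises(self, rng):
        t = rng.uniform(20, 60, (8, 8))
        with pytest.raises(ValueError):
            feature_loss(t, t, None)


class TestNetworkLoss:
    def test_reduces_to_l1_with_unit_weight(self, rng):
        t = rng.uniform(20, 60, (8, 8))
        p = t + rng.normal(0, 4, (8, 8))
        roi = np.ones((8, 8), bool)
        w = LossWeights(lam_l1=1.0, lam_l1_roi=0.0, lam_ssim=0.0,
                        lam_feature=0.0)
        total, comps = network_loss(t, p, roi, w, KNEE)
        assert total == pytest.approx(l1_scaled(t, p, KNEE), rel=1e-12)
        assert set(comps) == {"l1"}

    def test_zero_at_identity_for_any_weights(self, rng):
        t = rng.uniform(20, 60, (16, 16))
        roi = np.zeros((16, 16), bool)
        roi[4:8, 4:8] = True
        w = LossWeights(1.0, 75.0, 1.5, 0.25)
        total, _ = network_loss(t, t, roi, w, KNEE,
                                extractor=RandomConvFeatures(seed=1))
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_equals_hand_summed_components(self, rng):
        t = rng.uniform(20, 90, (16, 16))
        p = t + rng.normal(0, 6, (16, 16))
        roi = np.zeros((16, 16), bool)
        roi[2:10, 3:12] = True
        extractor = RandomConvFeatures(seed=2)
        w = LossWeights(1.0, 80.0, 1.2, 0.3)
        total, comps = network_loss(t, p, roi, w, KNEE, extractor=extractor)
        by_hand = (w.lam_l1 * l1_scaled(t, p, KNEE) +
                   w.lam_l1_roi * l1_scaled_roi(t, p, roi, KNEE) +
                   w.lam_ssim * ssim_loss(t, p, data_range=150.0) +
                   w.lam_feature * feature_loss(t, p, extractor,
                                                data_range=150.0))
        assert total == pytest.approx(by_hand, rel=1e-10)
        assert set(comps) == {"l1", "l1_roi", "ssim", "feature"}

    def test_component_nonnegativity(self, rng):
        t = rng.uniform(20, 60, (16, 16))
        p = rng.uniform(20, 60, (16, 16))
        roi = np.ones((16, 16), bool)
        _, comps = network_loss(t, p, roi, LossWeights(1, 50, 1, 0.1), KNEE,
                                extractor=RandomConvFeatures(seed=0))
        assert all(v >= 0 for v in comps.values())

    def test_autodiff_gradient_matches_finite_differences(self, rng):
        t = rng.uniform(20, 60, (8, 8))
        p0 = t + rng.normal(0, 4, (8, 8))
        roi = np.zeros((8, 8), bool)
        roi[2:6, 2:6] = True
        w = LossWeights(1.0, 60.0, 1.0, 0.2)
        extractor = RandomConvFeatures(seed=5)

        def loss_at(arr):
            total, _ = network_loss(t, arr, roi, w, KNEE, extractor=extractor)
            return total

        pt = Tensor(p0.copy(), requires_grad=True)
        total, _ = network_loss(t, pt, roi, w, KNEE, extractor=extractor)
        total.backward()
        eps = 1e-5
        for (i, j) in [(2, 3), (4, 4), (0, 0), (7, 5)]:
            pp, pm = p0.copy(), p0.copy()
            pp[i, j] += eps
            pm[i, j] -= eps
            num = (loss_at(pp) - loss_at(pm)) / (2 * eps)
            assert pt.grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_invalid_weight_combinations(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            LossWeights(-1.0, 1.0, 0.0, 0.0)
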