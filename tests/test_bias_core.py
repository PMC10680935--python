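"""Forward model, correction operator, masked losses, mean shift."""

import numpy as np
import pytest

from biasfield.core import (apply_bias, correct_with_field, loss_corrected,
                            loss_field, loss_gradient,
                            mean_shift_to_reference, total_loss)
from biasfield.volume import Mask, Volume


def _one_voxel_mask(shape, where=(0, 0, 0)):
    m = np.zeros(shape, dtype=bool)
    m[where] = True
    return Mask(m)


class TestForwardModel:
    def test_identity_field(self, rng):
        u = Volume(rng.random((8, 8, 8)))
        out = apply_bias(u, Volume(np.ones((8, 8, 8))))
        assert np.array_equal(out.data, u.data)

    def test_constant_product(self):
        u = np.full((4, 4, 4), 2.0)
        b = np.full((4, 4, 4), 3.0)
        assert np.allclose(apply_bias(u, b), 6.0)

    def test_log_identity(self, rng):
        u = rng.random((6, 6, 6)) + 0.5
        b = rng.random((6, 6, 6)) + 0.5
        lhs = np.log(apply_bias(u, b))
        assert np.max(np.abs(lhs - (np.log(u) + np.log(b)))) < 1e-10

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_bias(np.ones((4, 4, 4)), np.ones((5, 4, 4)))

    def test_exact_inverse_round_trip(self, small_sample):
        s = small_sample
        a = apply_bias(s.corrected_truth, s.field_truth)
        rec = correct_with_field(a, s.field_truth)
        m = s.mask.data
        rel = np.abs(rec.data[m] - s.corrected_truth.data[m]) \
            / np.abs(s.corrected_truth.data[m])
        assert rel.max() < 1e-6

    def test_zero_field_clamped_by_eps(self):
        a = np.ones((4, 4, 4))
        f = np.ones((4, 4, 4))
        f[0, 0, 0] = 0.0
        out = correct_with_field(a, f, eps=1e-6)
        assert np.isfinite(out).all()
        assert out[0, 0, 0] == pytest.approx(1e6)

    def test_scalar_division(self):
        out = correct_with_field(np.full((2, 2, 2), 6.0), np.full((2, 2, 2), 3.0))
        assert np.allclose(out, 2.0)

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            correct_with_field(np.ones((2, 2, 2)), np.ones((2, 2, 2)), eps=0)


class TestLosses:
    def test_zero_at_ground_truth(self, small_sample):
        s = small_sample
        logb = np.log(s.field_truth.data)
        assert loss_field(logb, s.field_truth, s.mask) == pytest.approx(0, abs=1e-12)
        lb = loss_corrected(s.acquired, logb, s.corrected_truth, s.mask)
        assert lb == pytest.approx(0, abs=1e-10)

    def test_single_voxel_field_loss(self):
        shape = (2, 2, 2)
        logb = np.zeros(shape)               # predicted field = 1
        b_true = np.full(shape, 2.0)
        m = _one_voxel_mask(shape)
        assert loss_field(logb, b_true, m) == pytest.approx(1.0, abs=1e-12)

    def test_single_voxel_corrected_loss(self):
        shape = (2, 2, 2)
        a = np.full(shape, 4.0)
        logb = np.full(shape, np.log(2.0))
        u = np.ones(shape)
        m = _one_voxel_mask(shape)
        # a / exp(logb) = 2, (2 - 1)^2 = 1
        assert loss_corrected(a, logb, u, m) == pytest.approx(1.0, abs=1e-12)

    def test_mean_normalization(self, rng):
        shape = (4, 4, 4)
        logb = rng.normal(0, 0.1, shape)
        b_true = np.exp(rng.normal(0, 0.1, shape))
        m1 = np.zeros(shape, dtype=bool)
        m1[:2] = True
        # identical per-voxel residuals duplicated into a doubled mask
        logb2 = np.concatenate([logb[:2], logb[:2]], axis=0)
        b2 = np.concatenate([b_true[:2], b_true[:2]], axis=0)
        m2 = np.ones_like(logb2, dtype=bool)
        l1 = loss_field(logb[:2] * 1.0, b_true[:2], Mask(np.ones((2, 4, 4), bool)))
        l2 = loss_field(logb2, b2, Mask(m2))
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_invariant_outside_mask(self, rng):
        shape = (4, 4, 4)
        a = rng.random(shape) + 0.5
        logb = rng.normal(0, 0.1, shape)
        u = rng.random(shape) + 0.5
        b = np.exp(rng.normal(0, 0.1, shape))
        m = np.zeros(shape, dtype=bool)
        m[1:3, 1:3, 1:3] = True
        la1 = loss_field(logb, b, Mask(m))
        lb1 = loss_corrected(a, logb, u, Mask(m))
        a2, logb2, u2, b2 = (x.copy() for x in (a, logb, u, b))
        a2[~m] = 99.0
        logb2[~m] = -5.0
        u2[~m] = 42.0
        b2[~m] = 7.0
        assert loss_field(logb2, b2, Mask(m)) == la1
        assert loss_corrected(a2, logb2, u2, Mask(m)) == lb1

    def test_empty_mask_rejected(self):
        m = Mask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError):
            loss_field(np.zeros((2, 2, 2)), np.ones((2, 2, 2)), m)

    def test_total_loss(self):
        assert total_loss(0.0, 0.0) == 0.0
        assert total_loss(1.5, 2.5) == 4.0

    def test_total_equals_components(self, noisy_sample, rng):
        s = noisy_sample
        logb = rng.normal(0, 0.1, s.acquired.shape)
        la = loss_field(logb, s.field_truth, s.mask)
        lb = loss_corrected(s.acquired, logb, s.corrected_truth, s.mask)
        la2, lb2, _ = loss_gradient(s.acquired.data, logb, s.field_truth.data,
                                    s.corrected_truth.data, s.mask)
        assert total_loss(la, lb) == pytest.approx(la2 + lb2, rel=1e-12)

    def test_gradient_matches_finite_differences(self, small_sample, rng):
        s = small_sample
        logb = rng.normal(0, 0.05, s.acquired.shape)
        la, lb, grad = loss_gradient(s.acquired.data, logb,
                                     s.field_truth.data,
                                     s.corrected_truth.data, s.mask)
        eps = 1e-6
        coords = np.argwhere(s.mask.data)[::97][:5]
        for c in map(tuple, coords):
            lp = logb.copy()
            lp[c] += eps
            la1, lb1, _ = loss_gradient(s.acquired.data, lp,
                                        s.field_truth.data,
                                        s.corrected_truth.data, s.mask)
            lm = logb.copy()
            lm[c] -= eps
            la2, lb2, _ = loss_gradient(s.acquired.data, lm,
                                        s.field_truth.data,
                                        s.corrected_truth.data, s.mask)
            num = ((la1 + lb1) - (la2 + lb2)) / (2 * eps)
            assert num == pytest.approx(grad[c], rel=1e-4, abs=1e-10)


class TestMeanShift:
    def test_noop_when_matching(self, rng):
        ref = rng.random((6, 6, 6))
        m = Mask(np.ones((6, 6, 6), bool))
        out = mean_shift_to_reference(ref.copy(), ref, m)
        assert np.allclose(out, ref, atol=1e-12)

    def test_constant_offset_removed(self, rng):
        ref = rng.random((6, 6, 6))
        m = Mask(np.ones((6, 6, 6), bool))
        out = mean_shift_to_reference(ref + 5.0, ref, m)
        assert np.allclose(out, ref, atol=1e-10)

    def test_shift_amount(self):
        shape = (4, 4, 4)
        img = np.full(shape, 2.0)
        ref = np.full(shape, 3.5)
        m = Mask(np.ones(shape, bool))
        out = mean_shift_to_reference(img, ref, m)
        assert np.allclose(out, 3.5)  # every voxel shifted by +1.5

    def test_masked_mean_matches_to_1e10(self, rng):
        img, ref = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        m = Mask(rng.random((8, 8, 8)) > 0.5)
        out = mean_shift_to_reference(img, ref, m)
        assert abs(out[m.data].mean() - ref[m.data].mean()) < 1e-10

    def test_idempotent(self, rng):
        img, ref = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        m = Mask(np.ones((8, 8, 8), bool))
        once = mean_shift_to_reference(img, ref, m)
        twice = mean_shift_to_reference(once, ref, m)
        assert np.allclose(once, twice, atol=1e-12)

    def test_multiplicative_mode(self, rng):
        img = rng.random((6, 6, 6)) + 0.5
        ref = rng.random((6, 6, 6)) + 0.5
        m = Mask(np.ones((6, 6, 6), bool))
        out = mean_shift_to_reference(img, ref, m, mode="multiplicative")
        assert out[m.data].mean() == pytest.approx(ref[m.data].mean(), rel=1e-10)
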