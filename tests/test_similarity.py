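import numpy as np
import pytest

from pseudoct import local_moments, mv_roi_lncc, plain_lncc, roi_lncc
from pseudoct.image_model import MaskKind, ROIMask

from conftest import make_volume, full_mask
from oracles import masked_lncc_bruteforce, masked_moments_bruteforce


def random_roi(rng, shape, fraction=0.5):
    return ROIMask(rng.random(shape) < fraction, (1.0, 1.0, 1.0),
                   (0.0, 0.0, 0.0), MaskKind.FOV_VALIDITY)


class TestLocalMoments:
    def test_constant_image_full_roi(self):
        vol = make_volume(np.full((10, 10, 10), 4.2))
        mom = local_moments(vol, full_mask((10, 10, 10)), sigma_mm=2.0)
        np.testing.assert_allclose(mom.mean, 4.2, atol=1e-12)
        np.testing.assert_allclose(mom.var, 0.0, atol=1e-12)
        assert mom.support.max() <= 1.0 + 1e-12

    def test_outside_roi_perturbation_leaves_interior_untouched(self):
        rng = np.random.default_rng(2)
        shape = (16, 16, 16)
        vals = rng.normal(size=shape)
        roi = np.zeros(shape, dtype=bool)
        roi[4:12, 4:12, 4:12] = True
        mask = ROIMask(roi, (1.0, 1.0, 1.0), (0, 0, 0), MaskKind.FOV_VALIDITY)
        m1 = local_moments(make_volume(vals), mask, sigma_mm=1.0)
        vals2 = vals.copy()
        vals2[~roi] += rng.normal(size=(~roi).sum()) * 100
        m2 = local_moments(make_volume(vals2), mask, sigma_mm=1.0)
        interior = m1.support > 0.99
        assert interior.any()
        np.testing.assert_allclose(m1.mean[interior], m2.mean[interior], atol=1e-10)
        np.testing.assert_allclose(m1.var[interior], m2.var[interior], atol=1e-10)

    def test_matches_bruteforce_windowed_sums(self):
        rng = np.random.default_rng(3)
        shape = (14, 14, 14)
        vals = rng.normal(size=shape)
        roi = rng.random(shape) < 0.7
        roi[5:9, 5:9, 5:9] = True
        mask = ROIMask(roi, (1.0, 1.0, 1.0), (0, 0, 0), MaskKind.FOV_VALIDITY)
        mom = local_moments(make_volume(vals), mask, sigma_mm=1.5)
        mean_o, var_o, support_o = masked_moments_bruteforce(vals, roi, (1.5, 1.5, 1.5))
        ok = support_o > 1e-3
        np.testing.assert_allclose(mom.mean[ok], mean_o[ok], atol=1e-6)
        np.testing.assert_allclose(mom.var[ok], var_o[ok], atol=1e-6)
        np.testing.assert_allclose(mom.support, support_o, atol=1e-6)

    def test_empty_roi_rejected(self):
        vol = make_volume(np.zeros((5, 5, 5)))
        empty = ROIMask(np.zeros((5, 5, 5), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            local_moments(vol, empty, sigma_mm=1.0)


class TestRoiLncc:
    def test_affine_intensity_relation_gives_one(self):
        rng = np.random.default_rng(4)
        t = make_volume(rng.normal(size=(12, 12, 12)))
        a = t.with_values(3.0 * t.values + 7.0)
        roi = full_mask((12, 12, 12))
        lncc, valid = roi_lncc(t, a, roi, roi, sigma_mm=2.0)
        assert valid.values.any()
        np.testing.assert_allclose(lncc[valid.values], 1.0, atol=1e-8)

    def test_negated_image_gives_minus_one(self):
        rng = np.random.default_rng(5)
        t = make_volume(rng.normal(size=(12, 12, 12)))
        a = t.with_values(-t.values)
        roi = full_mask((12, 12, 12))
        lncc, valid = roi_lncc(t, a, roi, roi, sigma_mm=2.0)
        np.testing.assert_allclose(lncc[valid.values], -1.0, atol=1e-8)

    def test_matches_bruteforce_on_half_roi(self):
        rng = np.random.default_rng(6)
        shape = (14, 14, 14)
        t = rng.normal(size=shape)
        a = rng.normal(size=shape)
        roi = np.zeros(shape, dtype=bool)
        roi[:, :7, :] = True
        mask = ROIMask(roi, (1.0, 1.0, 1.0), (0, 0, 0), MaskKind.FOV_VALIDITY)
        lncc, valid = roi_lncc(make_volume(t), make_volume(a), mask, mask,
                               sigma_mm=1.5)
        oracle, support = masked_lncc_bruteforce(t, a, roi, (1.5, 1.5, 1.5))
        np.testing.assert_allclose(lncc[valid.values], oracle[valid.values],
                                   atol=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        t = make_volume(rng.normal(size=(10, 10, 10)))
        a = make_volume(rng.normal(size=(10, 10, 10)))
        roi_t = random_roi(rng, (10, 10, 10), 0.8)
        roi_a = random_roi(rng, (10, 10, 10), 0.8)
        l1, v1 = roi_lncc(t, a, roi_t, roi_a, sigma_mm=1.5)
        l2, v2 = roi_lncc(a, t, roi_a, roi_t, sigma_mm=1.5)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_allclose(l1, l2, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        t = make_volume(rng.normal(size=(10, 10, 10)))
        a = make_volume(rng.normal(size=(10, 10, 10)))
        roi = full_mask((10, 10, 10))
        l1, v1 = roi_lncc(t, a, roi, roi, sigma_mm=1.5)
        l2, v2 = roi_lncc(t.with_values(5.0 * t.values),
                          a.with_values(0.3 * a.values), roi, roi, sigma_mm=1.5)
        np.testing.assert_allclose(l1[v1.values & v2.values],
                                   l2[v1.values & v2.values], atol=1e-10)

    def test_grid_mismatch_rejected(self):
        t = make_volume(np.zeros((6, 6, 6)))
        a = make_volume(np.zeros((6, 6, 6)), spacing=(2.0, 2.0, 2.0))
        roi = full_mask((6, 6, 6))
        with pytest.raises(ValueError, match="grid"):
            roi_lncc(t, a, roi, roi, sigma_mm=1.5)

    def test_values_bounded_and_neutral_outside_validity(self):
        rng = np.random.default_rng(9)
        t = make_volume(rng.normal(size=(12, 12, 12)))
        a = make_volume(rng.normal(size=(12, 12, 12)))
        roi = random_roi(rng, (12, 12, 12), 0.3)
        lncc, valid = roi_lncc(t, a, roi, roi, sigma_mm=1.0)
        assert np.all(np.abs(lncc) <= 1.0)
        np.testing.assert_array_equal(lncc[~valid.values], 0.0)


class TestMultivariate:
    def test_single_channel_reduces_to_roi_lncc(self):
        rng = np.random.default_rng(10)
        t = make_volume(rng.normal(size=(10, 10, 10)))
        a = make_volume(rng.normal(size=(10, 10, 10)))
        roi = full_mask((10, 10, 10))
        l1, v1 = roi_lncc(t, a, roi, roi, sigma_mm=1.5)
        l2, v2 = mv_roi_lncc([(t, a)], roi, roi, sigma_mm=1.5)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_allclose(l1, l2, atol=1e-15)

    def test_duplicated_channel_doubles_value(self):
        rng = np.random.default_rng(11)
        t = make_volume(rng.normal(size=(10, 10, 10)))
        a = make_volume(rng.normal(size=(10, 10, 10)))
        roi = full_mask((10, 10, 10))
        l1, v1 = roi_lncc(t, a, roi, roi, sigma_mm=1.5)
        l2, v2 = mv_roi_lncc([(t, a), (t, a)], roi, roi, sigma_mm=1.5)
        np.testing.assert_allclose(l2[v2.values], 2.0 * l1[v2.values], atol=1e-12)

    def test_sum_of_independent_channels(self):
        rng = np.random.default_rng(12)
        shape = (10, 10, 10)
        t1, a1 = make_volume(rng.normal(size=shape)), make_volume(rng.normal(size=shape))
        t2, a2 = make_volume(rng.normal(size=shape)), make_volume(rng.normal(size=shape))
        roi = full_mask(shape)
        s1, v1 = roi_lncc(t1, a1, roi, roi, sigma_mm=1.5)
        s2, v2 = roi_lncc(t2, a2, roi, roi, sigma_mm=1.5)
        total, v = mv_roi_lncc([(t1, a1), (t2, a2)], roi, roi, sigma_mm=1.5)
        both = v.values
        np.testing.assert_allclose(total[both], (s1 + s2)[both], atol=1e-12)

    def test_zero_channels_rejected(self):
        roi = full_mask((5, 5, 5))
        with pytest.raises(ValueError, match="at least one"):
            mv_roi_lncc([], roi, [], sigma_mm=1.5)


def test_plain_lncc_is_contaminated_by_fov_gaps():
    """The legacy full-grid LNCC changes when no-data voxels change; the ROI
    variant does not — the defining difference between the two."""
    rng = np.random.default_rng(13)
    shape = (16, 16, 16)
    t = rng.normal(size=shape)
    a = t + 0.1 * rng.normal(size=shape)
    roi = np.zeros(shape, dtype=bool)
    roi[:, :, 6:] = True
    a_fill = a.copy()
    a_fill[:, :, :6] = -50.0  # fill values in the missing-FOV zone
    mask = ROIMask(roi, (1, 1, 1), (0, 0, 0), MaskKind.FOV_VALIDITY)
    full = full_mask(shape)
    l_roi, v_roi = roi_lncc(make_volume(t), make_volume(a_fill), full, mask,
                            sigma_mm=2.0)
    l_plain, _ = plain_lncc(make_volume(t), make_volume(a_fill), sigma_mm=2.0)
    near = np.zeros(shape, dtype=bool)
    near[:, :, 6:9] = True
    near &= v_roi.values
    # ROI variant stays near 1 beside the gap, plain LNCC is dragged down
    assert l_roi[near].mean() > 0.8
    assert l_plain[near].mean() < l_roi[near].mean()


def test_information_free_channel_degrades_gracefully():
    """A locally constant second channel is invalid everywhere, so the
    multivariate similarity must reduce to the informative channel alone
    rather than losing all validity."""
    rng = np.random.default_rng(14)
    shape = (12, 12, 12)
    t1 = make_volume(rng.normal(size=shape))
    a1 = make_volume(rng.normal(size=shape))
    flat_t = make_volume(np.full(shape, 3.0))
    flat_a = make_volume(np.full(shape, -1.0))
    roi = full_mask(shape)
    single, v1 = roi_lncc(t1, a1, roi, roi, sigma_mm=1.5)
    total, v = mv_roi_lncc([(t1, a1), (flat_t, flat_a)], roi, roi, sigma_mm=1.5)
    np.testing.assert_array_equal(v.values, v1.values)
    np.testing.assert_allclose(total, single, atol=1e-12)
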