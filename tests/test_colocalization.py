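"""Mask-based colocalization coefficients and intensity correlation."""

import numpy as np
import pytest

from cshin.colocalization import (
    BinaryMask,
    ChannelImage,
    coloc_report,
    li_ica,
    make_mask,
    manders_intensity,
    manders_overlap,
    mask_product,
    pearson_r,
    roi_to_mask,
)
from cshin.synthetic_data import BeltPairSpec, make_belt_pair


class TestMakeMask:
    def test_constant_zero_image_all_background(self):
        mask = make_mask(ChannelImage(np.zeros((8, 8))), 10)
        assert not mask.pixels.any()
        assert mask.threshold_used == 10

    def test_threshold_comparison_is_strict(self):
        img = ChannelImage(np.full((4, 4), 7.0))
        assert not make_mask(img, 7).pixels.any()
        assert make_mask(img, 6.9).pixels.all()

    def test_otsu_recovers_bimodal_foreground_fraction(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(size=(100, 100)) < 0.3
        img = np.where(truth, 200.0, 20.0) + rng.normal(0, 5, size=(100, 100))
        mask = make_mask(ChannelImage(np.clip(img, 0, None)), "otsu")
        assert np.mean(mask.pixels) == pytest.approx(np.mean(truth), abs=0.01)

    def test_control_image_violation_warns(self):
        img = ChannelImage(np.full((10, 10), 100.0))
        dirty_control = ChannelImage(np.full((10, 10), 90.0))
        with pytest.warns(UserWarning, match="control"):
            make_mask(img, 50, control=dirty_control)

    def test_clean_control_is_silent(self):
        import warnings

        img = ChannelImage(np.full((10, 10), 100.0))
        clean = ChannelImage(np.zeros((10, 10)))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            make_mask(img, 50, control=clean)

    def test_strict_mode_rejects_empty_mask(self):
        with pytest.raises(ValueError, match="empty mask"):
            make_mask(ChannelImage(np.ones((4, 4))), 5, strict=True)


class TestMaskProduct:
    def test_idempotent_disjoint_commutative(self):
        rng = np.random.default_rng(1)
        a = BinaryMask(rng.uniform(size=(16, 16)) < 0.4)
        b = BinaryMask(rng.uniform(size=(16, 16)) < 0.4)
        assert np.array_equal(mask_product(a, a).pixels, a.pixels)
        assert np.array_equal(
            mask_product(a, b).pixels, mask_product(b, a).pixels
        )
        disjoint = BinaryMask(~a.pixels)
        assert not mask_product(a, disjoint).pixels.any()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mask_product(BinaryMask(np.ones((3, 3))), BinaryMask(np.ones((4, 4))))


class TestManders:
    def test_identical_and_disjoint_masks(self):
        a = BinaryMask(np.eye(5, dtype=bool))
        assert manders_overlap(a, a) == (1.0, 1.0)
        b = BinaryMask(~a.pixels)
        assert manders_overlap(a, b) == (0.0, 0.0)

    def test_three_by_three_toy_counts(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0, :3] = True
        a[1, 0] = True  # 4 positive
        b = np.zeros((3, 3), dtype=bool)
        b[0, 0] = True
        b[2, 2] = True  # 2 positive, overlap 1
        m1, m2 = manders_overlap(BinaryMask(a), BinaryMask(b))
        assert (m1, m2) == (0.25, 0.5)

    def test_empty_mask_is_explicit_error(self):
        a = BinaryMask(np.zeros((3, 3), dtype=bool))
        b = BinaryMask(np.ones((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="empty mask"):
            manders_overlap(a, b)

    def test_swapping_channels_swaps_m1_m2(self):
        rng = np.random.default_rng(2)
        a = BinaryMask(rng.uniform(size=(20, 20)) < 0.5)
        b = BinaryMask(rng.uniform(size=(20, 20)) < 0.3)
        m1, m2 = manders_overlap(a, b)
        m1s, m2s = manders_overlap(b, a)
        assert (m1, m2) == (m2s, m1s)

    def test_intensity_weighted_variant_identical_masks(self):
        rng = np.random.default_rng(3)
        img = ChannelImage(rng.uniform(10, 100, size=(10, 10)))
        full = BinaryMask(np.ones((10, 10), dtype=bool))
        assert manders_intensity(img, img, full, full) == (1.0, 1.0)


class TestPearson:
    def test_equal_and_inverted_channels(self):
        rng = np.random.default_rng(4)
        a = ChannelImage(rng.uniform(size=(30, 30)) * 100)
        assert pearson_r(a, a) == pytest.approx(1.0)
        inv = ChannelImage(a.pixels.max() - a.pixels)
        assert pearson_r(a, inv) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        a = ChannelImage(rng.uniform(size=(100, 100)))
        b = ChannelImage(rng.uniform(size=(100, 100)))
        assert abs(pearson_r(a, b)) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        a = ChannelImage(rng.uniform(size=(20, 20)) * 50)
        b = ChannelImage(rng.uniform(size=(20, 20)) * 50)
        r0 = pearson_r(a, b)
        assert pearson_r(ChannelImage(3.0 * a.pixels + 7.0), b) == pytest.approx(r0, abs=1e-12)
        assert pearson_r(a, ChannelImage(0.25 * b.pixels + 100.0)) == pytest.approx(r0, abs=1e-12)

    def test_constant_channel_is_error(self):
        a = ChannelImage(np.ones((5, 5)))
        b = ChannelImage(np.arange(25, dtype=float).reshape(5, 5))
        with pytest.raises(ValueError, match="constant"):
            pearson_r(a, b)

    def test_polygon_roi_restricts_pixels(self):
        a = np.zeros((20, 20))
        a[:10] = np.arange(200).reshape(10, 20)  # varies inside ROI
        b = a.copy()
        b[10:] = np.random.default_rng(1).uniform(size=(10, 20))
        roi = np.array([(0, 0), (19, 0), (19, 9), (0, 9)], dtype=float)
        r = pearson_r(ChannelImage(a), ChannelImage(np.clip(b, 0, None)), roi=roi)
        assert r == pytest.approx(1.0)


class TestLiICA:
    def test_equal_channels_icq_plus_half(self):
        rng = np.random.default_rng(7)
        a = ChannelImage(rng.uniform(size=(20, 20)) * 10)
        icq, pp = li_ica(a, a)
        assert icq == pytest.approx(0.5)

    def test_inverted_channel_icq_minus_half(self):
        rng = np.random.default_rng(8)
        a = ChannelImage(rng.uniform(size=(20, 20)) * 10)
        inv = ChannelImage(a.pixels.max() - a.pixels)
        icq, _ = li_ica(a, inv)
        assert icq == pytest.approx(-0.5)

    def test_independent_noise_icq_near_zero(self):
        rng = np.random.default_rng(9)
        a = ChannelImage(rng.uniform(size=(100, 100)))
        b = ChannelImage(rng.uniform(size=(100, 100)))
        icq, _ = li_ica(a, b)
        assert abs(icq) < 0.02

    def test_icq_invariant_under_increasing_affine_maps(self):
        rng = np.random.default_rng(10)
        a = ChannelImage(rng.uniform(size=(20, 20)) * 50)
        b = ChannelImage(rng.uniform(size=(20, 20)) * 50)
        icq0, _ = li_ica(a, b)
        icq1, _ = li_ica(ChannelImage(2.0 * a.pixels + 5.0), b)
        icq2, _ = li_ica(a, ChannelImage(0.1 * b.pixels + 3.0))
        assert icq1 == pytest.approx(icq0, abs=1e-12)
        assert icq2 == pytest.approx(icq0, abs=1e-12)

    def test_pp_mask_subset_of_positive_pdm(self):
        rng = np.random.default_rng(11)
        a = ChannelImage(rng.uniform(size=(30, 30)) * 100)
        b = ChannelImage(rng.uniform(size=(30, 30)) * 100)
        _, pp = li_ica(a, b)
        pdm = (a.pixels - a.pixels.mean()) * (b.pixels - b.pixels.mean())
        assert np.all(pdm[pp.pixels] > 0)

    def test_constant_channels_error(self):
        a = ChannelImage(np.full((4, 4), 3.0))
        with pytest.raises(ValueError, match="PDM"):
            li_ica(a, a)


class TestColocReport:
    def test_ground_truth_recovery_over_seeds(self):
        rho = 0.6
        m1s = []
        for seed in range(20):
            spec = BeltPairSpec(co_occurrence=rho, seed=seed)
            a, b, _ = make_belt_pair(spec)
            thr = (spec.fg_intensity + spec.bg_intensity) / 2
            m1s.append(coloc_report(a, b, thr, thr).m1)
        assert np.mean(m1s) == pytest.approx(rho, abs=0.05)

    def test_equal_channels_saturate_all_coefficients(self):
        rng = np.random.default_rng(12)
        a = ChannelImage(rng.uniform(size=(40, 40)) * 100 + 1)
        res = coloc_report(a, a, 50, 50)
        assert res.m1 == res.m2 == 1.0
        assert res.pearson_r == pytest.approx(1.0)
        assert res.li_icq == pytest.approx(0.5)

    def test_subthreshold_channel_raises_empty_mask_error(self):
        rng = np.random.default_rng(13)
        a = ChannelImage(rng.uniform(size=(20, 20)) * 100 + 50)
        noise = ChannelImage(rng.uniform(size=(20, 20)) * 5)
        with pytest.raises(ValueError, match="empty mask"):
            coloc_report(a, noise, 50, 50)

    def test_swap_symmetry(self):
        a, b, _ = make_belt_pair(BeltPairSpec(seed=4))
        r1 = coloc_report(a, b, 110, 110)
        r2 = coloc_report(b, a, 110, 110)
        assert (r1.m1, r1.m2, r1.n_a, r1.n_b) == (r2.m2, r2.m1, r2.n_b, r2.n_a)
        assert r1.pearson_r == pytest.approx(r2.pearson_r)
        assert r1.li_icq == pytest.approx(r2.li_icq)

    def test_pdm_route_agrees_with_mask_product_route(self):
        # on belt-pair defaults the ++PDM map and the mask product overlap
        # substantially (the two analysis routes converge)
        a, b, _ = make_belt_pair(BeltPairSpec(seed=5))
        res = coloc_report(a, b, 110, 110)
        pp, ov = res.pdm_pp_mask.pixels, res.overlap_mask.pixels
        jaccard = (pp & ov).sum() / (pp | ov).sum()
        assert jaccard >= 0.5


class TestRoi:
    def test_none_selects_everything(self):
        assert roi_to_mask(None, (4, 5)).all()

    def test_mask_roi_shape_checked(self):
        with pytest.raises(ValueError):
            roi_to_mask(BinaryMask(np.ones((3, 3), dtype=bool)), (4, 4))

    def test_polygon_roi_uses_pixel_centers(self):
        roi = np.array([(0.5, 0.5), (3.5, 0.5), (3.5, 3.5), (0.5, 3.5)])
        sel = roi_to_mask(roi, (6, 6))
        assert sel[1:4, 1:4].all()
        assert sel.sum() == 9
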