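import numpy as np
import pytest
from scipy import ndimage

from retmodal import he_seg
from retmodal.he_seg import (
    SaliencyConfig,
    SaliencyMap,
    apply_correction,
    rgb_to_lab,
    saliency_at_scale,
    saliency_multiscale,
    segment_he,
)
from retmodal.phantom import PhantomConfig, generate_case


def naive_saliency(lab, half, width):
    """Independent double-loop center-surround contrast with symmetric padding."""
    outer = half + width
    padded = np.pad(lab, ((outer, outer), (outer, outer), (0, 0)), mode="symmetric")
    nx, ny = lab.shape[:2]
    out = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            ci, cj = i + outer, j + outer
            inner = padded[ci - half : ci + half + 1, cj - half : cj + half + 1]
            big = padded[ci - outer : ci + outer + 1, cj - outer : cj + outer + 1]
            v1 = inner.reshape(-1, 3).mean(axis=0)
            n_in = (2 * half + 1) ** 2
            n_out = (2 * outer + 1) ** 2
            v2 = (big.reshape(-1, 3).sum(axis=0) - inner.reshape(-1, 3).sum(axis=0)) / (
                n_out - n_in
            )
            out[i, j] = np.linalg.norm(v1 - v2)
    return out


class TestRgbToLab:
    def test_black_white_and_gray_anchors(self):
        img = np.array([[[0, 0, 0], [255, 255, 255], [128, 128, 128]]], dtype=np.uint8)
        lab = rgb_to_lab(img)
        assert lab[0, 0, 0] == pytest.approx(0.0, abs=1e-6)
        assert lab[0, 1, 0] == pytest.approx(100.0, abs=1e-3)
        # neutral axis: a and b vanish for any gray
        np.testing.assert_allclose(lab[0, :, 1:], 0.0, atol=0.02)

    def test_midgray_lightness_from_independent_colorimetry(self):
        # L* = 116 f(Y/Yn) - 16 with the standard sRGB linearisation
        srgb = 128 / 255
        lin = ((srgb + 0.055) / 1.055) ** 2.4
        fy = lin ** (1 / 3) if lin > (6 / 29) ** 3 else lin / (3 * (6 / 29) ** 2) + 4 / 29
        expected_l = 116 * fy - 16
        lab = rgb_to_lab(np.full((1, 1, 3), 128, dtype=np.uint8))
        assert lab[0, 0, 0] == pytest.approx(expected_l, abs=1e-3)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            rgb_to_lab(np.zeros((4, 4)))


class TestSaliency:
    def test_uniform_image_gives_zero_map(self):
        lab = np.full((20, 20, 3), 37.0)
        for h in (1, 2, 3):
            np.testing.assert_allclose(saliency_at_scale(lab, h), 0.0, atol=1e-12)

    def test_single_pixel_contrast_is_euclidean_norm(self):
        # v1=[60,0,0] vs v2=[50,0,0] -> C = 10
        lab = np.full((11, 11, 3), 50.0)
        lab[4:7, 4:7, 0] = 60.0  # inner 3x3 square at h=1
        c = saliency_at_scale(lab, 1, 1)
        # center pixel: inner mean L=60, annulus mean L=50
        assert c[5, 5] == pytest.approx(10.0)

    @pytest.mark.parametrize("h,w", [(1, 1), (1, 2), (2, 2), (3, 3)])
    def test_matches_naive_double_loop(self, rng, h, w):
        lab = rng.uniform(0, 100, size=(12, 12, 3))
        got = saliency_at_scale(lab, h, w)
        np.testing.assert_allclose(got, naive_saliency(lab, h, w), atol=1e-9)

    def test_multiscale_total_is_elementwise_sum(self, rng):
        lab = rng.uniform(0, 100, size=(16, 16, 3))
        cfg = SaliencyConfig(scales=(1, 3))
        smap = saliency_multiscale(lab, cfg)
        np.testing.assert_allclose(smap.total, smap.per_scale[0] + smap.per_scale[1])
        single = saliency_multiscale(lab, SaliencyConfig(scales=(2,)))
        np.testing.assert_allclose(single.total, single.per_scale[0])

    def test_channel_shift_invariance(self, rng):
        lab = rng.uniform(0, 100, size=(14, 14, 3))
        shifted = lab.copy()
        shifted[:, :, 0] += 17.0
        a = saliency_multiscale(lab, SaliencyConfig(scales=(1, 2)))
        b = saliency_multiscale(shifted, SaliencyConfig(scales=(1, 2)))
        np.testing.assert_allclose(a.total, b.total, atol=1e-9)

    def test_total_dominates_each_scale_and_is_nonnegative(self, rng):
        lab = rng.uniform(0, 100, size=(16, 16, 3))
        smap = saliency_multiscale(lab, SaliencyConfig(scales=(1, 2, 3)))
        assert (smap.total >= -1e-12).all()
        for c in smap.per_scale:
            assert (smap.total - c >= -1e-9).all()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            saliency_at_scale(np.zeros((6, 6, 3)), 3, 4)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            SaliencyConfig(scales=(3, 3))
        with pytest.raises(ValueError, match="nonempty"):
            SaliencyConfig(scales=())
        with pytest.raises(ValueError, match="fixed_threshold"):
            SaliencyConfig(threshold_method="fixed")


class TestSegmentHE:
    def test_zero_map_with_fixed_threshold_gives_empty_mask(self):
        smap = SaliencyMap(per_scale=[np.zeros((8, 8))], total=np.zeros((8, 8)))
        cfg = SaliencyConfig(threshold_method="fixed", fixed_threshold=0.5)
        assert segment_he(smap, cfg).sum() == 0

    def test_constant_map_with_otsu_advises_fixed(self):
        smap = SaliencyMap(per_scale=[np.ones((8, 8))], total=np.ones((8, 8)))
        with pytest.raises(ValueError, match="fixed"):
            segment_he(smap, SaliencyConfig())

    def test_bright_disc_on_dark_fundus(self):
        img = np.zeros((120, 120, 3))
        img[:] = (30, 20, 15)
        yy, xx = np.mgrid[:120, :120]
        disc = (yy - 60) ** 2 + (xx - 60) ** 2 <= 8**2
        img[disc] = (245, 220, 120)
        cfg = SaliencyConfig()
        mask = segment_he(saliency_multiscale(rgb_to_lab(img), cfg), cfg).astype(bool)
        _, n = ndimage.label(mask, np.ones((3, 3)))
        assert n == 1
        dice = 2 * (mask & disc).sum() / (mask.sum() + disc.sum())
        assert dice >= 0.8

    def test_phantom_exudates_with_vessels_component_count(self):
        cfg = PhantomConfig(
            grid_dims=(128, 32, 256), n_foci=8, n_exudates=4, rng_seed=3
        )
        case = generate_case(cfg, "e", "PDR")
        sal = SaliencyConfig()
        mask = segment_he(
            saliency_multiscale(rgb_to_lab(case.fundus.rgb), sal), sal
        )
        _, n = ndimage.label(mask, np.ones((3, 3)))
        assert n == 4

    def test_raising_fixed_threshold_never_adds_pixels(self, rng):
        total = rng.uniform(0, 10, size=(20, 20))
        smap = SaliencyMap(per_scale=[total], total=total)
        prev = None
        for thr in (1.0, 3.0, 5.0, 8.0):
            cfg = SaliencyConfig(
                threshold_method="fixed", fixed_threshold=thr, min_area_px=1
            )
            mask = segment_he(smap, cfg).astype(bool)
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask


class TestApplyCorrectionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    masks = hnp.arrays(np.uint8, (6, 6), elements=st.integers(0, 1))

    @settings(derandomize=True, max_examples=50)
    @given(masks, masks, masks)
    def test_set_algebra_semantics(self, mask, add, remove):
        out = apply_correction(mask, add, remove).astype(bool)
        expected = (mask.astype(bool) | add.astype(bool)) & ~remove.astype(bool)
        np.testing.assert_array_equal(out, expected)


class TestApplyCorrection:
    def test_no_op_masks_are_identity(self, rng):
        mask = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        zero = np.zeros_like(mask)
        np.testing.assert_array_equal(apply_correction(mask, zero, zero), mask)

    def test_removing_everything_empties_mask(self, rng):
        mask = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        assert apply_correction(mask, remove_mask=mask).sum() == 0

    def test_disjoint_add_increases_popcount_exactly(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[0, 0] = 1
        add = np.zeros_like(mask)
        add[3:5, 3:5] = 1  # 4 disjoint pixels
        assert apply_correction(mask, add_mask=add).sum() == 5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            apply_correction(np.zeros((4, 4)), add_mask=np.zeros((3, 3)))
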