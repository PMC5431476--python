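from collections import deque

import numpy as np
import pytest

from retmodal.hrf_seg import (
    adaptive_seeds,
    detect_hrf,
    height_map,
    link_3d,
    region_grow,
    split_by_he,
)
from retmodal.oct_layers import build_surfaces
from retmodal.phantom import PhantomConfig, generate_case


def flood_fill_count(mask):
    """Independent 26-connected component count by BFS."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        q = deque([start])
        seen[start] = True
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)):
                    if mask[p] and not seen[p]:
                        seen[p] = True
                        q.append(p)
    return count


class TestAdaptiveSeeds:
    def test_constant_band_yields_no_seeds(self):
        bscan = np.full((10, 20), 50.0)
        band = np.ones_like(bscan, dtype=bool)
        assert adaptive_seeds(bscan, band, k=2.0).sum() == 0

    def test_single_outlier_pixel_is_the_only_seed(self):
        # 99 pixels at 50, one at 255: mu+2sigma lies below 255 only
        bscan = np.full((10, 10), 50.0)
        bscan[3, 7] = 255.0
        band = np.ones_like(bscan, dtype=bool)
        vals = bscan[band]
        thr = vals.mean() + 2.0 * vals.std()
        assert 50 < thr < 255  # sanity of the construction
        seeds = adaptive_seeds(bscan, band, k=2.0)
        assert seeds.sum() == 1
        assert seeds[3, 7] == 1

    def test_very_negative_k_seeds_whole_band(self, rng):
        bscan = rng.uniform(0, 255, size=(8, 8))
        band = rng.random((8, 8)) > 0.4
        seeds = adaptive_seeds(bscan, band, k=-1e9)
        np.testing.assert_array_equal(seeds.astype(bool), band)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adaptive_seeds(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))


class TestRegionGrow:
    def test_empty_seeds_give_empty_mask(self):
        out = region_grow(
            np.zeros((6, 6)), np.zeros((6, 6)), np.ones((6, 6), dtype=bool)
        )
        assert out.sum() == 0

    def test_bright_square_fully_recovered_from_one_seed(self):
        bscan = np.full((12, 12), 30.0)
        bscan[4:9, 4:9] = 120.0
        seeds = np.zeros_like(bscan)
        seeds[6, 6] = 1
        band = np.ones_like(bscan, dtype=bool)
        out = region_grow(bscan, seeds, band, delta=10.0)
        assert out.sum() == 25
        assert out[4:9, 4:9].all()

    def test_growth_never_leaves_band(self, rng):
        for _ in range(5):
            bscan = rng.uniform(0, 255, size=(16, 16))
            band = rng.random((16, 16)) > 0.3
            seeds = (rng.random((16, 16)) > 0.8) & band
            out = region_grow(bscan, seeds, band, delta=50.0).astype(bool)
            assert not (out & ~band).any()

    def test_seeds_outside_band_rejected(self):
        seeds = np.ones((4, 4))
        with pytest.raises(ValueError, match="inside"):
            region_grow(np.zeros((4, 4)), seeds, np.zeros((4, 4), dtype=bool))


class TestLink3D:
    def test_single_voxel_lesion(self):
        masks = [np.zeros((5, 8), dtype=bool) for _ in range(3)]
        masks[1][2, 4] = True
        lesions = link_3d(masks)
        assert len(lesions) == 1
        assert lesions.lesions[0].centroid == (2.0, 1.0, 4.0)

    def test_diagonal_voxels_in_adjacent_bscans_link(self):
        masks = [np.zeros((5, 8), dtype=bool) for _ in range(2)]
        masks[0][2, 4] = True
        masks[1][3, 5] = True  # diagonal in all three axes
        assert len(link_3d(masks)) == 1

    def test_component_count_matches_flood_fill(self, rng):
        for _ in range(5):
            vol = rng.random((12, 6, 12)) > 0.8
            lesions = link_3d([vol[:, y, :] for y in range(vol.shape[1])])
            assert len(lesions) == flood_fill_count(vol)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            link_3d([np.zeros((4, 4)), np.zeros((4, 5))])

    def test_column_extents_sum_to_voxel_count(self, rng):
        vol = rng.random((10, 4, 10)) > 0.7
        lesions = link_3d([vol[:, y, :] for y in range(4)])
        for les in lesions.lesions:
            assert les.column_counts.sum() == les.n_voxels


class TestHeightMap:
    def test_empty_set_gives_zero_map(self):
        lesions = link_3d([np.zeros((6, 6), dtype=bool)])
        np.testing.assert_array_equal(height_map(lesions, 1.953), 0.0)

    def test_ten_voxel_column_height(self):
        masks = [np.zeros((4, 20), dtype=bool)]
        masks[0][2, 5:15] = True  # 10 voxels in one column
        lesions = link_3d(masks)
        hm = height_map(lesions, 2000.0 / 1024)
        assert hm[2, 0] == pytest.approx(19.53, abs=0.01)

    def test_mass_conservation(self, rng):
        vol = rng.random((10, 5, 12)) > 0.75
        lesions = link_3d([vol[:, y, :] for y in range(5)])
        hm = height_map(lesions, 1.953)
        assert hm.sum() / 1.953 == pytest.approx(vol.sum())


class TestSplitByHE:
    @staticmethod
    def _two_lesions():
        masks = [np.zeros((10, 10), dtype=bool) for _ in range(2)]
        masks[0][1:3, 2:4] = True
        masks[1][7:9, 5:7] = True
        return link_3d(masks)

    def test_empty_he_mask_gives_all_foci(self):
        lesions = self._two_lesions()
        he, foci = split_by_he(lesions, np.zeros((10, 2), dtype=np.uint8))
        assert len(he) == 0
        assert len(foci) == 2

    def test_footprint_inside_mask_is_he(self):
        lesions = self._two_lesions()
        he_mask = np.zeros((10, 2), dtype=np.uint8)
        he_mask[1:3, 0] = 1  # covers lesion 1's footprint (bscan 0)
        he, foci = split_by_he(lesions, he_mask)
        assert len(he) == 1 and len(foci) == 1

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        vol = rng.random((12, 4, 12)) > 0.8
        lesions = link_3d([vol[:, y, :] for y in range(4)])
        he_mask = (rng.random((12, 4)) > 0.5).astype(np.uint8)
        he, foci = split_by_he(lesions, he_mask)
        assert len(he) + len(foci) == len(lesions)
        assert not (he.mask().astype(bool) & foci.mask().astype(bool)).any()
        np.testing.assert_array_equal(
            he.mask() | foci.mask(), lesions.mask()
        )

    def test_frame_mismatch_rejected(self):
        lesions = self._two_lesions()
        with pytest.raises(ValueError, match="frame"):
            split_by_he(lesions, np.zeros((5, 5), dtype=np.uint8))


class TestPhantomDetection:
    def test_five_foci_recovered_with_dice(self, small_case):
        surf = build_surfaces(small_case.oct)
        lesions = detect_hrf(small_case.oct, surf, k=4.0, delta=10.0)
        assert len(lesions) == small_case.config.n_foci
        labels = small_case.truth_foci_labels
        for lid in range(1, small_case.config.n_foci + 1):
            tm = labels == lid
            ids, counts = np.unique(
                lesions.labels[tm & (lesions.labels > 0)], return_counts=True
            )
            assert len(ids), f"truth focus {lid} entirely missed"
            best = ids[np.argmax(counts)]
            dm = lesions.labels == best
            dice = 2 * np.logical_and(tm, dm).sum() / (tm.sum() + dm.sum())
            assert dice >= 0.7

    def test_all_lesions_inside_narrow_band(self, small_case):
        surf = build_surfaces(small_case.oct)
        from retmodal.oct_layers import build_narrow_band

        band = build_narrow_band(surf, small_case.oct.shape, 2)
        lesions = detect_hrf(small_case.oct, surf, k=4.0, band=band)
        assert not (lesions.mask().astype(bool) & ~band.mask).any()

    def test_he_classification_agrees_with_truth(self, small_case):
        surf = build_surfaces(small_case.oct)
        lesions = detect_hrf(small_case.oct, surf, k=4.0)
        he, foci = split_by_he(lesions, small_case.truth_he_mask_enface)
        truth_he = small_case.truth_foci_labels * 0
        for lid in small_case.truth_he_focus_ids:
            truth_he |= (small_case.truth_foci_labels == lid).astype(np.int32)
        # every detected HE lesion overlaps a truth HE focus and vice versa
        agree = 0
        for les in he.lesions:
            vox = les.voxels
            agree += int(truth_he[vox[:, 0], vox[:, 1], vox[:, 2]].any())
        assert len(he) == len(small_case.truth_he_focus_ids)
        assert agree == len(he)
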