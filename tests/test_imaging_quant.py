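"""Confocal quantification: density, 3-D puncta, CTCF, normalization."""

import numpy as np
import pytest

from ontosleep import imaging_quant as iq
from ontosleep.synthetic_data import simulate_image_stack


def blob_stack(blobs, shape=(8, 20, 20), intensity=60.0):
    """Stack with rectangular blobs given as (z, y, x) slice triples."""
    vox = np.zeros(shape)
    for zs, ys, xs in blobs:
        vox[zs, ys, xs] = intensity
    return iq.ImageStack(voxels=vox)


def full_roi(shape=(8, 20, 20)):
    return iq.RoiMask(mask=np.ones(shape, dtype=bool))


class TestInnervationDensity:
    def test_saturated_roi_is_one(self):
        img = np.full((10, 10), 100.0)
        assert iq.innervation_density(img, iq.RoiMask(np.ones((10, 10), bool)), 52) == 1.0

    def test_empty_signal_is_zero(self):
        img = np.zeros((10, 10))
        assert iq.innervation_density(img, iq.RoiMask(np.ones((10, 10), bool)), 52) == 0.0

    def test_half_covered_roi_is_exactly_half(self):
        img = np.zeros((10, 10))
        img[:5] = 80.0
        assert iq.innervation_density(img, iq.RoiMask(np.ones((10, 10), bool)), 52) == 0.5

    def test_threshold_is_inclusive(self):
        img = np.full((4, 4), 52.0)
        assert iq.innervation_density(img, iq.RoiMask(np.ones((4, 4), bool)), 52) == 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(iq.RoiError):
            iq.innervation_density(np.zeros((5, 5)), iq.RoiMask(np.zeros((5, 5), bool)), 52)

    def test_monotone_non_increasing_in_threshold(self, rng):
        img = rng.uniform(0, 100, size=(20, 20))
        roi = iq.RoiMask(np.ones((20, 20), bool))
        densities = [iq.innervation_density(img, roi, t) for t in range(0, 101, 5)]
        assert all(a >= b for a, b in zip(densities, densities[1:]))


class TestCountPuncta3d:
    def test_seven_disjoint_blobs_counted(self):
        blobs = [
            (slice(z, z + 1), slice(y, y + 2), slice(x, x + 5))
            for z, y, x in [(0, 0, 0), (2, 4, 4), (4, 8, 8), (6, 12, 12),
                            (1, 16, 2), (3, 0, 12), (5, 16, 14)]
        ]
        stack = blob_stack(blobs)
        res = iq.count_puncta_3d(stack, full_roi())
        assert res.count == 7
        assert np.all(res.sizes == 10)

    def test_single_voxel_below_min_size_excluded(self):
        stack = blob_stack([(slice(2, 3), slice(5, 6), slice(5, 6))])
        assert iq.count_puncta_3d(stack, full_roi()).count == 0

    def test_oversized_blob_excluded(self):
        stack = blob_stack([(slice(0, 1), slice(0, 10), slice(0, 10))])  # 100 voxels
        assert iq.count_puncta_3d(stack, full_roi()).count == 0

    def test_inclusive_size_bounds(self):
        stack = blob_stack([
            (slice(0, 1), slice(0, 1), slice(0, 2)),    # 2 voxels
            (slice(4, 5), slice(4, 12), slice(4, 14)),  # 80 voxels
        ])
        assert iq.count_puncta_3d(stack, full_roi()).count == 2

    def test_min_above_max_rejected(self):
        stack = blob_stack([])
        with pytest.raises(ValueError):
            iq.count_puncta_3d(stack, full_roi(), min_size=10, max_size=2)

    def test_density_times_volume_is_count(self):
        stack, roi, truth = simulate_image_stack(5, seed=11)
        res = iq.count_puncta_3d(stack, roi)
        assert res.count == len(truth)
        assert res.density_per_voxel * res.roi_volume_voxels == pytest.approx(res.count)
        assert res.roi_volume_voxels == int(roi.mask.sum())

    def test_invariant_under_axis_permutation(self):
        stack, roi, truth = simulate_image_stack(6, seed=3)
        base = iq.count_puncta_3d(stack, roi).count
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = iq.ImageStack(np.transpose(stack.voxels, perm))
            roi_p = iq.RoiMask(np.transpose(roi.mask, perm))
            assert iq.count_puncta_3d(permuted, roi_p).count == base

    def test_invariant_under_subthreshold_padding(self):
        stack, roi, truth = simulate_image_stack(4, seed=9)
        base = iq.count_puncta_3d(stack, roi).count
        padded_vox = np.pad(stack.voxels, 2, constant_values=5.0)
        padded_roi = np.pad(roi.mask, 2, constant_values=True)
        res = iq.count_puncta_3d(iq.ImageStack(padded_vox), iq.RoiMask(padded_roi))
        assert res.count == base

    def test_26_connectivity_merges_diagonal_voxels(self):
        vox = np.zeros((4, 4, 4))
        vox[0, 0, 0] = vox[1, 1, 1] = 60.0  # touching only diagonally
        stack = iq.ImageStack(vox)
        res = iq.count_puncta_3d(stack, iq.RoiMask(np.ones((4, 4, 4), bool)))
        assert res.count == 1  # one 2-voxel object under 26-connectivity
        res6 = iq.count_puncta_3d(
            stack, iq.RoiMask(np.ones((4, 4, 4), bool)), connectivity=6
        )
        assert res6.count == 0  # two 1-voxel objects, both below min size


class TestCtcf:
    def test_formula_arithmetic(self):
        assert iq.ctcf(5000.0, 100.0, 10.0) == 4000.0

    def test_cell_equal_to_background_is_zero(self):
        img = np.full((10, 10), 7.0)
        cell = iq.RoiMask(np.zeros((10, 10), bool), label="cell")
        cell.mask[2:5, 2:5] = True
        bg = iq.RoiMask(np.zeros((10, 10), bool), label="background")
        bg.mask[7:, 7:] = True
        assert iq.ctcf_from_rois(img, cell, bg) == pytest.approx(0.0)

    def test_zero_background_leaves_integrated_density(self):
        assert iq.ctcf(1234.5, 50.0, 0.0) == 1234.5

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            iq.ctcf(100.0, 0.0, 1.0)

    def test_linear_in_integrated_density_and_background(self, rng):
        area = 37.0
        base = iq.ctcf(1000.0, area, 5.0)
        assert iq.ctcf(1000.0 + 10.0, area, 5.0) - base == pytest.approx(10.0)
        assert iq.ctcf(1000.0, area, 5.0 + 1.0) - base == pytest.approx(-area)


class TestNormalizedRoiSignal:
    def test_ratio_arithmetic(self):
        res = iq.normalized_roi_signal(80.0, 40.0, "adjacent_background")
        assert res.ratio == 2.0
        assert res.mode == "adjacent_background"

    def test_equal_signal_and_reference_is_unity(self):
        assert iq.normalized_roi_signal(33.0, 33.0, "same_roi_reference").ratio == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            iq.normalized_roi_signal(10.0, 0.0, "adjacent_background")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            iq.normalized_roi_signal(1.0, 1.0, "whole_brain")

    def test_constructed_single_section_ratios(self):
        img = np.zeros((12, 12))
        img[:6] = 90.0   # signal region
        img[6:] = 30.0   # reference region
        sig_roi = iq.RoiMask(np.zeros((12, 12), bool))
        sig_roi.mask[:6] = True
        ref_roi = iq.RoiMask(np.zeros((12, 12), bool))
        ref_roi.mask[6:] = True
        sig = iq.roi_mean(img, sig_roi)
        ref = iq.roi_mean(img, ref_roi)
        assert iq.normalized_roi_signal(sig, ref, "adjacent_background").ratio == 3.0


class TestInnervationPresence:
    def _cohort(self, densities):
        items = []
        for d in densities:
            img = np.zeros((10, 10))
            img[: int(round(d * 10))] = 100.0
            items.append((img, iq.RoiMask(np.ones((10, 10), bool))))
        return items

    def test_all_positive_is_hundred_percent(self):
        res = iq.innervation_presence(self._cohort([0.9] * 10), 52, 0.1)
        assert res.fraction == 1.0 and res.n_positive == 10

    def test_none_positive_is_zero_percent(self):
        res = iq.innervation_presence(self._cohort([0.0] * 10), 52, 0.1)
        assert res.fraction == 0.0

    def test_four_of_ten_is_forty_percent_with_ci(self):
        res = iq.innervation_presence(
            self._cohort([0.5] * 4 + [0.0] * 6), 52, 0.1
        )
        assert res.fraction == pytest.approx(0.4)
        assert res.ci_low < 0.4 < res.ci_high

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            iq.innervation_presence([], 52, 0.1)


class TestTiffIO:
    def test_stack_and_roi_round_trip(self, tmp_path):
        stack, roi, _ = simulate_image_stack(3, seed=5)
        iq.save_stack(stack, tmp_path / "s.tif")
        back = iq.load_stack(tmp_path / "s.tif")
        assert np.allclose(back.voxels, stack.voxels)
        import tifffile

        tifffile.imwrite(tmp_path / "r.tif", (roi.mask * 255).astype(np.uint8))
        roi_back = iq.load_roi(tmp_path / "r.tif")
        assert np.array_equal(roi_back.mask, roi.mask)
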