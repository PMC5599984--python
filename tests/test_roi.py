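import numpy as np
import pytest

from hippot2.image_core import LabelMask, VolumetricImage
from hippot2.phantom import LABELS
from hippot2.relaxometry import T2Map
from hippot2.roi import (
    EmptyRoiError,
    RoiPolicy,
    erode_mask,
    exclude_csf,
    measure_roi,
    slice_profile,
    summarize_roi,
)

from _oracles import brute_force_erode


def _mask(vox):
    return LabelMask(voxels=np.asarray(vox), affine=np.eye(4))


def _t2map(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return T2Map(
        t2=VolumetricImage(
            voxels=np.where(valid, values, np.nan), affine=np.eye(4)
        ),
        valid=valid,
    )


class TestErosion:
    def test_square_label_shrinks_by_one_ring(self):
        vox = np.zeros((7, 7, 3), dtype=np.int16)
        vox[1:6, 1:6, 1] = 1  # 5x5 in-plane square
        out = erode_mask(_mask(vox), RoiPolicy(erosion_iterations=1))
        expected = np.zeros_like(vox)
        expected[2:5, 2:5, 1] = 1  # 3x3
        np.testing.assert_array_equal(out.voxels, expected)

    def test_one_voxel_thick_plane_vanishes(self):
        vox = np.zeros((7, 7, 3), dtype=np.int16)
        vox[3, 1:6, 1] = 1
        out = erode_mask(_mask(vox), RoiPolicy())
        assert not out.voxels.any()

    def test_zero_iterations_is_identity(self):
        vox = np.zeros((5, 5, 3), dtype=np.int16)
        vox[1:4, 1:4, 1] = 2
        out = erode_mask(_mask(vox), RoiPolicy(erosion_iterations=0))
        np.testing.assert_array_equal(out.voxels, vox)

    def test_labels_eroded_independently(self):
        vox = np.zeros((9, 9, 3), dtype=np.int16)
        vox[1:5, 1:8, 1] = 1
        vox[5:8, 1:8, 1] = 2  # touching label 1
        out = erode_mask(_mask(vox), RoiPolicy())
        # label 1 keeps nothing of row 4 (it borders label 2, not itself)
        assert set(np.unique(out.voxels)) <= {0, 1, 2}
        assert (out.voxels[vox == 2] != 1).all()

    @pytest.mark.parametrize("mode", ["in-plane", "full-3d"])
    def test_matches_brute_force_neighbourhood_oracle(self, rng, mode):
        vox = (rng.random((16, 16, 8)) > 0.55).astype(np.int16)
        policy = RoiPolicy(erosion_mode=mode)
        out = erode_mask(_mask(vox), policy)
        expected = brute_force_erode(
            vox.astype(bool), policy.structuring_element()
        )
        np.testing.assert_array_equal(out.voxels.astype(bool), expected)

    def test_erosion_is_subset_and_strict_with_boundary(self, rng):
        vox = np.zeros((12, 12, 6), dtype=np.int16)
        vox[2:10, 3:9, 1:5] = 1
        out = erode_mask(_mask(vox), RoiPolicy())
        assert np.all(vox[out.voxels > 0] > 0)  # subset
        assert np.count_nonzero(out.voxels) < np.count_nonzero(vox)


class TestCsfExclusion:
    def test_threshold_is_strict(self):
        vox = np.ones((1, 1, 3), dtype=np.int16)
        t2map = _t2map(np.array([[[169.0, 170.0, 171.0]]]))
        out = exclude_csf(_mask(vox), t2map, RoiPolicy())
        np.testing.assert_array_equal(out.voxels.ravel(), [1, 1, 0])

    def test_mask_below_threshold_unchanged(self):
        vox = np.ones((2, 2, 2), dtype=np.int16)
        t2map = _t2map(np.full((2, 2, 2), 120.0))
        out = exclude_csf(_mask(vox), t2map, RoiPolicy())
        np.testing.assert_array_equal(out.voxels, vox)

    def test_invalid_voxels_are_excluded(self):
        vox = np.ones((1, 1, 2), dtype=np.int16)
        t2map = _t2map(np.array([[[100.0, np.nan]]]))
        out = exclude_csf(_mask(vox), t2map, RoiPolicy())
        np.testing.assert_array_equal(out.voxels.ravel(), [1, 0])

    def test_phantom_csf_voxels_all_removed(self, phantom_clean, t2map_clean):
        """Ground-truth CSF voxels inside the overreaching segmentation are
        eliminated by the 170 msec threshold (CSF T2 = 2000 msec)."""
        seg = phantom_clean.segmentation
        out = exclude_csf(seg, t2map_clean, RoiPolicy())
        csf = phantom_clean.truth_labels.voxels == LABELS["csf"]
        assert (seg.voxels[csf] > 0).any()  # contamination present going in
        assert not (out.voxels[csf] > 0).any()


class TestSummarize:
    def test_uniform_roi_is_exact(self):
        vox = np.zeros((4, 4, 2), dtype=np.int16)
        vox[1:3, 1:3, :] = 1
        t2map = _t2map(np.full((4, 4, 2), 115.0))
        res = summarize_roi(_mask(vox), t2map, RoiPolicy(min_voxels=1))
        assert res[1].mean_t2 == 115.0
        assert res[1].sd_t2 == 0.0

    def test_two_voxel_roi_hand_arithmetic(self):
        vox = np.zeros((1, 1, 2), dtype=np.int16)
        vox[0, 0, :] = 1
        t2map = _t2map(np.array([[[100.0, 120.0]]]))
        res = summarize_roi(_mask(vox), t2map, RoiPolicy(min_voxels=1))
        assert res[1].mean_t2 == pytest.approx(110.0)
        assert res[1].sd_t2 == pytest.approx(np.sqrt(200.0), abs=1e-9)  # 14.142

    def test_empty_roi_raises_with_label(self):
        vox = np.zeros((2, 2, 2), dtype=np.int16)
        vox[0, 0, 0] = 3
        t2map = _t2map(np.full((2, 2, 2), np.nan))
        with pytest.raises(EmptyRoiError, match="label 3"):
            summarize_roi(_mask(vox), t2map, RoiPolicy())

    def test_small_roi_flagged_unreliable(self):
        vox = np.zeros((2, 2, 2), dtype=np.int16)
        vox[0, 0, :] = 1
        t2map = _t2map(np.full((2, 2, 2), 100.0))
        res = summarize_roi(_mask(vox), t2map, RoiPolicy(min_voxels=20))
        assert not res[1].reliable

    def test_noisy_phantom_roi_mean_close_to_truth(
        self, phantom_noisy, t2map_noisy
    ):
        """At late-echo SNR ~ 50 a few-hundred-voxel eroded, CSF-excluded
        hippocampal ROI recovers true T2 within 1.5 msec."""
        res = measure_roi(phantom_noisy.segmentation, t2map_noisy)
        for label in (1, 2):
            assert res[label].n_voxels >= 200
            assert abs(res[label].mean_t2 - 115.0) < 1.5


class TestPipelineOrder:
    def test_counts_shrink_monotonically_and_stay_inside_segmentation(
        self, phantom_clean, t2map_clean
    ):
        seg = phantom_clean.segmentation
        policy = RoiPolicy()
        eroded = erode_mask(seg, policy)
        cleaned = exclude_csf(eroded, t2map_clean, policy)
        for label in (1, 2):
            assert seg.count(label) >= eroded.count(label) >= cleaned.count(label)
        assert np.all(seg.voxels[cleaned.voxels > 0] > 0)

    def test_noiseless_processing_removes_csf_bias_exactly(
        self, phantom_clean, t2map_clean
    ):
        """Unprocessed segmentation mean is inflated by CSF partial volume;
        the eroded + thresholded mean equals true hippocampal T2 exactly."""
        seg = phantom_clean.segmentation
        raw = summarize_roi(seg, t2map_clean, RoiPolicy())
        processed = measure_roi(seg, t2map_clean, RoiPolicy())
        for label in (1, 2):
            assert raw[label].mean_t2 > 115.0
            assert processed[label].mean_t2 == pytest.approx(115.0, abs=1e-9)


class TestSliceProfile:
    def test_uniform_phantom_profile_is_flat(self, phantom_clean, t2map_clean):
        seg = phantom_clean.segmentation
        policy = RoiPolicy()
        cleaned = exclude_csf(erode_mask(seg, policy), t2map_clean, policy)
        prof = slice_profile(cleaned, t2map_clean, policy, label=1)
        np.testing.assert_allclose(prof.mean_t2_per_slice, 115.0)

    def test_anteroposterior_step_recovered(self):
        from hippot2.phantom import PhantomSpec, generate_phantom
        from hippot2.relaxometry import fit_t2_map

        phantom = generate_phantom(
            PhantomSpec(
                shape=(80, 80, 20),
                noise_sigma=0.0,
                t2_hippocampus_anterior=125.0,
                t2_hippocampus_posterior=115.0,
            )
        )
        t2map = fit_t2_map(phantom.acquisition)
        policy = RoiPolicy()
        cleaned = exclude_csf(
            erode_mask(phantom.segmentation, policy), t2map, policy
        )
        prof = slice_profile(cleaned, t2map, policy, label=1)
        anterior = prof.slice_index < 10
        np.testing.assert_allclose(prof.mean_t2_per_slice[anterior], 125.0)
        np.testing.assert_allclose(prof.mean_t2_per_slice[~anterior], 115.0)

    def test_weighted_profile_mean_equals_pooled_roi_mean(
        self, phantom_noisy, t2map_noisy
    ):
        seg = phantom_noisy.segmentation
        policy = RoiPolicy()
        cleaned = exclude_csf(erode_mask(seg, policy), t2map_noisy, policy)
        prof = slice_profile(cleaned, t2map_noisy, policy, label=2)
        pooled = summarize_roi(cleaned, t2map_noisy, policy, labels=[2])[2]
        assert prof.pooled_mean() == pytest.approx(pooled.mean_t2, rel=1e-12)

    def test_empty_structure_raises(self):
        vox = np.zeros((2, 2, 2), dtype=np.int16)
        vox[0, 0, 0] = 1
        t2map = _t2map(np.full((2, 2, 2), np.nan))
        with pytest.raises(EmptyRoiError):
            slice_profile(_mask(vox), t2map, RoiPolicy(), label=1)
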