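"""Cavity classification operators (steps 7-14) and pipeline invariants."""

import numpy as np
import pytest
from scipy import ndimage

from ramps.cavity import (
    CavityNotFoundError,
    PriorSet,
    RescaledVolume,
    directional_boundary_dilation,
    expand_cavity,
    finalize_mask,
    kmeans2_csf,
    prior_mixture_segment,
    remove_misalignment_spurs,
    rescale_unit,
    subtract_images,
)
from ramps.core import BinaryMask, ResectionSpec, Volume
from ramps.metrics import compare_masks
from ramps.preprocess import (
    build_lobe_atlas,
    dilate_atlas_through_wm,
    split_resection_lobes,
)

EYE = np.eye(4)


def _vol(data):
    return Volume(np.asarray(data, float), EYE)


def _mask(data):
    return BinaryMask(np.asarray(data, bool), EYE)


# ---------------------------------------------------------------------------
# step 7
# ---------------------------------------------------------------------------

class TestRescale:
    def test_three_value_brain_maps_to_unit_interval(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [10.0, 15.0, 20.0]
        brain = _mask(np.ones((3, 1, 1)))
        out = rescale_unit(_vol(data), brain)
        assert np.allclose(out.data[:, 0, 0], [0.0, 0.5, 1.0], atol=0.02)

    def test_global_gain_invariance(self, small_case):
        pre, _, truth = small_case
        brain = _mask(truth.region_labels.data > 0)
        a = rescale_unit(pre, brain)
        b = rescale_unit(_vol(pre.data * 3.7), brain)
        assert np.allclose(a.data, b.data, atol=1e-5)

    def test_range_and_background(self, small_case):
        pre, _, truth = small_case
        brain = _mask(truth.region_labels.data > 0)
        out = rescale_unit(pre, brain)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0
        assert np.all(out.data[~brain.data] == 0.0)

    def test_constant_brain_rejected(self):
        brain = _mask(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="constant"):
            rescale_unit(_vol(np.full((4, 4, 4), 2.0)), brain)


# ---------------------------------------------------------------------------
# step 8
# ---------------------------------------------------------------------------

def _priors_from_truth(truth, affine):
    brain = BinaryMask(truth.region_labels.data > 0, affine)
    atlas = build_lobe_atlas(truth.region_labels)
    full = dilate_atlas_through_wm(atlas, brain)
    target, others = split_resection_lobes(full, ResectionSpec("L", "T"))
    vent = BinaryMask(np.isin(truth.region_labels.data, (4, 43)), affine)
    return PriorSet(vent, others, target), brain


class TestPriorMixture:
    def test_recovers_cavity_on_aligned_phantom(self, small_case):
        pre, post, truth = small_case
        priors, brain = _priors_from_truth(truth, pre.affine)
        seg = prior_mixture_segment(rescale_unit(post, brain), priors)
        dsc = compare_masks(truth.resection_mask, seg).dsc
        assert dsc >= 0.90

    def test_tissue_like_search_region_yields_empty(self):
        rng = np.random.default_rng(0)
        data = np.zeros((12, 12, 12))
        data[0:4] = rng.normal(0.05, 0.01, (4, 12, 12))     # "ventricles"
        data[4:8] = rng.normal(0.8, 0.02, (4, 12, 12))      # tissue prior
        data[8:12] = rng.normal(0.8, 0.02, (4, 12, 12))     # search: tissue
        csf = np.zeros((12, 12, 12), bool); csf[0:4] = True
        tis = np.zeros((12, 12, 12), bool); tis[4:8] = True
        sea = np.zeros((12, 12, 12), bool); sea[8:12] = True
        seg = prior_mixture_segment(
            RescaledVolume(np.clip(data, 0, 1), EYE),
            PriorSet(_mask(csf), _mask(tis), _mask(sea)))
        assert seg.count() == 0

    def test_overlapping_priors_warn(self):
        rng = np.random.default_rng(1)
        data = np.clip(rng.normal(0.5, 0.05, (12, 12, 12)), 0, 1)
        csf = np.zeros((12, 12, 12), bool); csf[0:4] = True
        tis = np.zeros((12, 12, 12), bool); tis[4:8] = True
        sea = np.zeros((12, 12, 12), bool); sea[8:12] = True
        with pytest.warns(UserWarning, match="overlap"):
            prior_mixture_segment(RescaledVolume(data, EYE),
                                  PriorSet(_mask(csf), _mask(tis), _mask(sea)))

    def test_disjointness_enforced(self):
        a = np.zeros((4, 4, 4), bool); a[0] = True
        with pytest.raises(ValueError, match="disjoint"):
            PriorSet(_mask(a), _mask(a), _mask(~a))


# ---------------------------------------------------------------------------
# step 9
# ---------------------------------------------------------------------------

class TestKmeansCsf:
    @staticmethod
    def _brute_force_2means(vals):
        """Oracle: try every threshold split, pick the partition that
        2-means converges to from the 25/75 percentile start."""
        centers = np.percentile(vals, [25, 75])
        for _ in range(100):
            assign = np.abs(vals - centers[0]) > np.abs(vals - centers[1])
            new = [vals[~assign].mean(), vals[assign].mean()]
            if np.allclose(new, centers):
                break
            centers = new
        return assign

    def test_low_cluster_returned(self):
        data = np.zeros((20, 1, 1))
        data[:10, 0, 0] = 0.05
        data[10:, 0, 0] = 0.5
        cav = _mask(np.ones((20, 1, 1)))
        out = kmeans2_csf(RescaledVolume(data, EYE), cav, min_separation=0.0)
        assert out.count() == 10
        assert np.all(data[out.data] == pytest.approx(0.05))
        vals = data[cav.data]
        assign = self._brute_force_2means(vals)
        # oracle agrees: the low-valued half is one cluster
        assert set(vals[~assign]) == {0.05} or set(vals[assign]) == {0.05}

    def test_result_is_subset_of_cavity(self, small_case):
        pre, post, truth = small_case
        priors, brain = _priors_from_truth(truth, pre.affine)
        post_r = rescale_unit(post, brain)
        cav = prior_mixture_segment(post_r, priors)
        with pytest.warns(UserWarning, match="single distinct"):
            out = kmeans2_csf(post_r, cav)  # noiseless cavity is constant
        assert not np.any(out.data & ~cav.data)

    def test_single_intensity_returns_whole_with_warning(self):
        data = np.full((10, 1, 1), 0.3)
        cav = _mask(np.ones((10, 1, 1)))
        with pytest.warns(UserWarning, match="single distinct"):
            out = kmeans2_csf(RescaledVolume(data, EYE), cav)
        assert out.count() == 10

    def test_unimodal_cavity_not_halved(self):
        rng = np.random.default_rng(2)
        data = np.clip(rng.normal(0.1, 0.02, (8, 8, 8)), 0, 1)
        cav = _mask(np.ones((8, 8, 8)))
        out = kmeans2_csf(RescaledVolume(data, EYE), cav)
        assert out.count() == cav.count()


# ---------------------------------------------------------------------------
# step 10
# ---------------------------------------------------------------------------

class TestSubtract:
    def test_identical_images_cancel(self, small_case):
        pre, _, truth = small_case
        brain = _mask(truth.region_labels.data > 0)
        pre_r = rescale_unit(pre, brain)
        diff = subtract_images(pre_r, pre_r, brain)
        assert np.all(diff.data == 0.0)

    def test_tissue_over_csf_is_positive_and_background_zero(self):
        pre = RescaledVolume(np.full((6, 6, 6), 1.0), EYE)
        post = RescaledVolume(np.zeros((6, 6, 6)), EYE)
        brain = np.zeros((6, 6, 6), bool)
        brain[2:4] = True
        diff = subtract_images(pre, post, _mask(brain))
        assert np.all(diff.data[brain] == 1.0)
        assert np.all(diff.data[~brain] == 0.0)


# ---------------------------------------------------------------------------
# step 11
# ---------------------------------------------------------------------------

class TestExpandCavity:
    def test_isolated_seed_blob_returned(self):
        diff = np.zeros((20, 20, 20))
        seed = np.zeros((20, 20, 20), bool)
        seed[8:12, 8:12, 8:12] = True
        diff[seed] = 0.8
        lobe = np.ones((20, 20, 20), bool)
        out = expand_cavity(_vol(diff), _mask(seed), _mask(lobe))
        assert np.array_equal(out.data, seed)

    def test_largest_component_kept(self):
        """Oracle: independent component labelling of the class-1 voxels."""
        diff = np.zeros((30, 30, 30))
        big = np.zeros((30, 30, 30), bool)
        big[2:10, 2:10, 2:10] = True       # 512 voxels
        small = np.zeros((30, 30, 30), bool)
        small[20:24, 20:24, 20:23] = True  # 48 voxels
        diff[big | small] = 0.8
        seed = np.zeros((30, 30, 30), bool)
        seed[3:6, 3:6, 3:6] = True
        seed[21:23, 21:23, 21:22] = True   # seed in both blobs
        out = expand_cavity(_vol(diff), _mask(seed),
                            _mask(np.ones((30, 30, 30))))
        lab, n = ndimage.label(big | small, structure=np.ones((3, 3, 3)))
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        oracle = lab == (1 + int(np.argmax(sizes)))
        assert np.array_equal(out.data, oracle)

    def test_output_within_lobe(self):
        diff = np.zeros((16, 16, 16))
        diff[4:12, 4:12, 4:12] = 0.9
        seed = np.zeros((16, 16, 16), bool)
        seed[6:8, 6:8, 6:8] = True
        lobe = np.zeros((16, 16, 16), bool)
        lobe[4:12, 4:12, 4:8] = True
        out = expand_cavity(_vol(diff), _mask(seed), _mask(lobe))
        assert not np.any(out.data & ~lobe)

    def test_empty_seed_raises(self):
        with pytest.raises(CavityNotFoundError, match="no cavity"):
            expand_cavity(_vol(np.zeros((8, 8, 8))),
                          _mask(np.zeros((8, 8, 8))),
                          _mask(np.ones((8, 8, 8))))


# ---------------------------------------------------------------------------
# step 12
# ---------------------------------------------------------------------------

class TestSpurRemoval:
    def test_solid_cube_unchanged(self):
        data = np.zeros((16, 16, 16), bool)
        data[3:13, 3:13, 3:13] = True
        out = remove_misalignment_spurs(_mask(data))
        assert np.array_equal(out.data, data)

    def test_bridge_and_small_attachment_removed(self):
        data = np.zeros((30, 16, 16), bool)
        data[2:10, 4:12, 4:12] = True           # 8^3 blob
        data[16:21, 6:11, 6:11] = True          # smaller blob
        data[10:16, 7, 7] = True                # 1-voxel bridge, 6 long
        out = remove_misalignment_spurs(_mask(data), cluster_threshold=10)
        expected = np.zeros_like(data)
        expected[2:10, 4:12, 4:12] = True
        assert np.array_equal(out.data, expected)

    def test_output_subset_of_input(self, pipeline_a):
        _, state, _ = pipeline_a
        assert not np.any(state.cleaned_mask.data & ~state.expanded_mask.data)

    def test_tiny_mask_protected(self):
        data = np.zeros((10, 10, 10), bool)
        data[4, 4, 4:6] = True
        with pytest.warns(UserWarning, match="skipping spur removal"):
            out = remove_misalignment_spurs(_mask(data))
        assert np.array_equal(out.data, data)


# ---------------------------------------------------------------------------
# step 13
# ---------------------------------------------------------------------------

class TestBoundaryDilation:
    def test_gap_of_two_fills_intermediate_voxel(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[2:5, 5, 5] = True
        csf = np.zeros((12, 12, 12), bool)
        csf[6, 5, 5] = True  # 2 voxels beyond the boundary voxel (4,5,5)
        out = directional_boundary_dilation(_mask(mask), _mask(csf))
        assert out.data[5, 5, 5]
        assert not out.data[6, 5, 5]  # the CSF voxel itself is not added
        assert out.count() == mask.sum() + 1

    def test_no_csf_nearby_leaves_mask_unchanged(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[4:7, 4:7, 4:7] = True
        csf = np.zeros((12, 12, 12), bool)
        csf[11, 11, 11] = True
        out = directional_boundary_dilation(_mask(mask), _mask(csf))
        assert np.array_equal(out.data, mask)

    def test_added_voxels_within_chebyshev_bound(self, pipeline_a):
        _, state, _ = pipeline_a
        added = state.dilated_mask.data & ~state.cleaned_mask.data
        if not added.any():
            return
        boundary = state.cleaned_mask.data & ~ndimage.binary_erosion(
            state.cleaned_mask.data)
        dist = ndimage.distance_transform_cdt(~boundary, metric="chessboard")
        assert dist[added].max() <= 3


# ---------------------------------------------------------------------------
# step 14
# ---------------------------------------------------------------------------

def _flood_fill_oracle(mask):
    """Hole filling by explicit border flood fill of the background."""
    bg = ~mask
    lab, n = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
    border_labels = set(np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(),
        lab[:, -1].ravel(), lab[:, :, 0].ravel(), lab[:, :, -1].ravel()])))
    filled = mask.copy()
    for comp in range(1, n + 1):
        if comp not in border_labels:
            filled |= lab == comp
    return filled


class TestFinalize:
    def test_hollow_shell_becomes_solid(self):
        data = np.zeros((15, 15, 15), bool)
        data[3:12, 3:12, 3:12] = True
        data[4:11, 4:11, 4:11] = False  # hollow it
        lobe = _mask(np.ones((15, 15, 15)))
        out = finalize_mask(_mask(data), lobe)
        assert np.array_equal(out.data, _flood_fill_oracle(data))
        assert out.data[7, 7, 7]  # centre filled

    def test_outside_lobe_removed(self):
        data = np.zeros((12, 12, 12), bool)
        data[2:10, 2:10, 2:10] = True
        lobe = np.zeros((12, 12, 12), bool)
        lobe[2:10, 2:10, 2:6] = True
        out = finalize_mask(_mask(data), _mask(lobe))
        assert not np.any(out.data & ~lobe)

    def test_identity_resample_when_grids_match(self):
        data = np.zeros((10, 10, 10), bool)
        data[3:7, 3:7, 3:7] = True
        out = finalize_mask(_mask(data), _mask(np.ones((10, 10, 10))),
                            original_grid=(EYE, (10, 10, 10)))
        assert np.array_equal(out.data, data)

    def test_entirely_outside_lobe_raises(self):
        data = np.zeros((10, 10, 10), bool)
        data[2:5, 2:5, 2:5] = True
        lobe = np.zeros((10, 10, 10), bool)
        lobe[8, 8, 8] = True
        with pytest.raises(CavityNotFoundError, match="outside specified"):
            finalize_mask(_mask(data), _mask(lobe))


# ---------------------------------------------------------------------------
# pipeline invariants
# ---------------------------------------------------------------------------

class TestPipelineInvariants:
    def test_containment_chain(self, pipeline_a, case_a):
        _, state, _ = pipeline_a
        assert not np.any(state.cleaned_mask.data & ~state.expanded_mask.data)
        assert np.all(state.dilated_mask.data[state.cleaned_mask.data])

    def test_final_mask_single_component(self, pipeline_a):
        final, _, _ = pipeline_a
        _, n = ndimage.label(final.data, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_final_mask_in_lobe_and_brain(self, pipeline_a, case_a):
        final, _, _ = pipeline_a
        _, _, truth = case_a
        brain = truth.region_labels.data > 0
        assert not np.any(final.data & ~brain)
        # left-hemisphere resection stays in the left hemisphere
        mid = final.shape[0] // 2
        assert not np.any(final.data[mid + 2:])

    def test_wrong_lobe_spec_fails_loudly(self, case_a):
        from ramps.cavity import run_cavity_pipeline

        pre, post, truth = case_a
        with pytest.raises((CavityNotFoundError, ValueError)):
            run_cavity_pipeline(pre, post, truth.region_labels,
                                truth.region_labels_post,
                                ResectionSpec("R", "O"))

    def test_non_isotropic_input_normalized_and_mapped_back(self):
        """A 2 mm acquisition is resampled to the 1 mm working grid and
        the final mask returns to the original grid."""
        import dataclasses

        from ramps.cavity import run_cavity_pipeline
        from ramps.phantom import generate_case, preset_config

        cfg = dataclasses.replace(
            preset_config("a", seed=1, grid_shape=(48, 48, 48)),
            voxel_spacing=(2.0, 2.0, 2.0))
        pre, post, truth = generate_case(cfg)
        final, _, report = run_cavity_pipeline(
            pre, post, truth.region_labels, truth.region_labels_post,
            ResectionSpec("L", "T"))
        assert report["steps"]["working_grid"] == [96, 96, 96]
        assert final.shape == (48, 48, 48)
        assert compare_masks(truth.resection_mask, final).dsc >= 0.8
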