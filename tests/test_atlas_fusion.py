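"""Label fusion, volumetry and the multi-atlas segmentation pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mamvol.atlas_fusion import (
    AtlasSet,
    FusionError,
    compute_icv,
    compute_volumes,
    dice_coefficient,
    majority_vote,
    propagate_atlases,
    segment_mb,
)
from mamvol.phantom_forge import ground_truth_labels, make_atlas_set
from mamvol.volgrid_io import (
    GeometryMismatchError,
    LabelMap,
    resample_isotropic,
)


def _maps_from_votes(votes: np.ndarray) -> list[LabelMap]:
    """votes: (n_maps, n_voxels) label array -> single-row LabelMaps."""
    n_maps, n_vox = votes.shape
    return [
        LabelMap(votes[i].reshape(n_vox, 1, 1), spacing_mm=np.ones(3))
        for i in range(n_maps)
    ]


def _bruteforce_vote(pattern: tuple[int, ...]) -> int:
    # oracle: strict majority over the raw pattern
    n = len(pattern)
    for lab in (1, 2):
        if pattern.count(lab) > n / 2:
            return lab
    return 0


class TestMajorityVote:
    def test_exhaustive_five_map_patterns(self):
        patterns = list(itertools.product((0, 1, 2), repeat=5))
        votes = np.array(patterns).T  # (5 maps, 243 voxels)
        fused = majority_vote(_maps_from_votes(votes))
        expect = np.array([_bruteforce_vote(p) for p in patterns])
        np.testing.assert_array_equal(fused.labels.reshape(-1), expect)

    @pytest.mark.parametrize(
        "pattern,expected",
        [((1, 1, 1, 2, 0), 1), ((1, 1, 2, 2, 0), 0), ((2, 2, 2, 2, 2), 2), ((0, 0, 1, 1, 0), 0)],
    )
    def test_named_patterns(self, pattern, expected):
        fused = majority_vote(_maps_from_votes(np.array(pattern).reshape(-1, 1)))
        assert fused.labels.reshape(-1)[0] == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.integers(3, 7),
        st.integers(0, 2**31 - 1),
    )
    def test_random_stacks_match_bruteforce(self, n_maps, seed):
        r = np.random.default_rng(seed)
        votes = r.integers(0, 3, size=(n_maps, 64))
        fused = majority_vote(_maps_from_votes(votes)).labels.reshape(-1)
        expect = [_bruteforce_vote(tuple(votes[:, v])) for v in range(64)]
        np.testing.assert_array_equal(fused, expect)

    def test_needs_three_maps(self):
        with pytest.raises(FusionError):
            majority_vote(_maps_from_votes(np.array([[1], [2]])))

    def test_geometry_mismatch_rejected(self):
        maps = _maps_from_votes(np.array([[1], [1], [1]]))
        bad = LabelMap(maps[0].labels, spacing_mm=2 * np.ones(3))
        with pytest.raises(GeometryMismatchError):
            majority_vote([maps[0], maps[1], bad])


class TestVolumetry:
    def test_volume_is_count_times_voxel_volume(self):
        arr = np.zeros((20, 10, 10), dtype=int)
        arr.reshape(-1)[:600] = 1
        lab = LabelMap(arr, spacing_mm=0.5 * np.ones(3))
        left, right = compute_volumes(lab)
        assert left == 600 * 0.125 == 75.0
        assert right == 0.0

    def test_discretized_ellipsoid_volume(self, clean_spec):
        from mamvol.phantom_forge import build_phantom
        from dataclasses import replace

        spec = replace(clean_spec, grid_shape=(128, 128, 128), spacing_mm=0.5)
        _, lab = build_phantom(spec)
        left, right = compute_volumes(lab)
        analytic = 4 / 3 * np.pi * 2.5 * 1.5 * 1.5
        assert abs(left - analytic) / analytic < 0.10
        assert abs(right - analytic) / analytic < 0.10

    def test_icv_of_phantom_head(self, clean_spec, clean_phantom):
        img, _ = clean_phantom
        mask = LabelMap(
            (img.voxels > 50).astype(int), img.spacing_mm, img.origin_mm, img.orientation
        )
        icv = compute_icv(mask)
        analytic = 4 / 3 * np.pi * np.prod(clean_spec.head_semiaxes_mm) / 1000.0
        assert abs(icv - analytic) / analytic < 0.05

    def test_icv_empty_mask_rejected(self):
        with pytest.raises(FusionError):
            compute_icv(LabelMap(np.zeros((4, 4, 4), dtype=int)))

    def test_icv_scales_with_voxel_volume(self):
        arr = np.ones((6, 6, 6), dtype=int)
        a = compute_icv(LabelMap(arr, spacing_mm=np.ones(3)))
        b = compute_icv(LabelMap(arr, spacing_mm=2 * np.ones(3)))
        assert b == pytest.approx(8 * a)


class TestSegmentationPipeline:
    def test_atlas_set_requires_both_labels(self, atlas_samples):
        bad = LabelMap(
            (atlas_samples[0].labels.labels == 1).astype(int),
            atlas_samples[0].labels.spacing_mm,
        )
        with pytest.raises(FusionError):
            AtlasSet(((atlas_samples[0].image, bad),))

    def test_self_registration_recovers_own_labels(self, atlas_set):
        # subject IS the first atlas image: its propagated labels must
        # agree with its own labels away from the one-voxel boundary
        # shell, where nearest-neighbor rounding of a near-identity
        # transform is inherently ambiguous
        from scipy import ndimage

        from mamvol.volgrid_io import resample_labels

        img, lab = atlas_set.atlases[0]
        subject = resample_isotropic(img, 0.5)
        maps = propagate_atlases(subject, AtlasSet((atlas_set.atlases[0],) * 3))
        ref = resample_labels(lab, 0.5)
        for l in (1, 2):
            ref_mask = ref.labels == l
            prop_mask = maps[0].labels == l
            # shell width = one SOURCE voxel (labels live on the 1 mm
            # atlas grid = 2 voxels of the 0.5 mm analysis grid)
            shell = ndimage.binary_dilation(ref_mask, iterations=2) & ~ndimage.binary_erosion(
                ref_mask, iterations=2
            )
            keep = ~shell
            a, b = ref_mask & keep, prop_mask & keep
            dice = 2 * np.count_nonzero(a & b) / (a.sum() + b.sum())
            assert dice > 0.95

    def test_per_atlas_dice_above_half(self, segmented_subject, atlas_set):
        sample, gt, result = segmented_subject
        subject = resample_isotropic(sample.image, 0.5)
        maps = propagate_atlases(subject, atlas_set)
        assert len(maps) == 5
        for m in maps:
            for l in (1, 2):
                assert dice_coefficient(m, gt, l) > 0.5

    def test_fused_segmentation_accuracy(self, segmented_subject):
        _, gt, result = segmented_subject
        vv = gt.voxel_volume_mm3
        for l, vol in ((1, result.left_volume_mm3), (2, result.right_volume_mm3)):
            assert dice_coefficient(result.fused, gt, l) >= 0.7
            gt_vol = np.count_nonzero(gt.labels == l) * vv
            assert abs(vol - gt_vol) / gt_vol <= 0.15

    def test_result_volumes_consistent_with_fused_map(self, segmented_subject):
        _, _, result = segmented_subject
        left, right = compute_volumes(result.fused)
        assert result.left_volume_mm3 == left
        assert result.right_volume_mm3 == right
        assert result.n_atlases_used == 5

    def test_fused_label_backed_by_majority(self, segmented_subject):
        _, _, result = segmented_subject
        votes = result.per_atlas_votes
        fused = result.fused.labels
        for l in (1, 2):
            assert np.all(votes[..., l][fused == l] > result.n_atlases_used / 2)

    def test_accuracy_improves_with_smaller_deformation(self, base_spec, atlas_set):
        from mamvol.phantom_forge import DeformationSpec

        dices = []
        for amp in (3.0, 1.5, 0.0):
            subj = make_atlas_set(
                base_spec, k=1, deform=DeformationSpec(amplitude_mm=amp), seed=55
            )[0]
            res = segment_mb(subj.image, atlas_set)
            gt = ground_truth_labels(base_spec, subj, 0.5)
            dices.append(
                0.5 * (dice_coefficient(res.fused, gt, 1) + dice_coefficient(res.fused, gt, 2))
            )
        assert dices[0] <= dices[1] + 0.05 and dices[1] <= dices[2] + 0.05
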