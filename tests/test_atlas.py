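import numpy as np
import pytest

from lcseg.atlas import (AtlasSegmenter, DemonsParams, apply_atlas,
                         build_fuzzy_atlas, demons_register, warp_volume)
from lcseg.evaluation import binarize_lcc, dice
from lcseg.io_core import BinaryMask, SoftMask, Volume
from lcseg.phase import normalize_std

from conftest import make_volume


class TestFuzzyAtlas:
    def test_identical_cases_give_the_common_mask(self, cohort6):
        atlas = build_fuzzy_atlas([cohort6[0]] * 3)
        assert np.array_equal(atlas.fuzzy_left.data,
                              cohort6[0].mask_left.data.astype(float))

    def test_two_disjoint_single_voxel_masks_average_to_half(self, cohort6):
        import copy

        a = copy.copy(cohort6[0])
        b = copy.copy(cohort6[1])
        m1 = np.zeros(a.image.shape); m1[10, 10, 10] = 1
        m2 = np.zeros(a.image.shape); m2[20, 20, 20] = 1
        a.mask_left = BinaryMask(m1.astype(np.uint8), a.image.affine.copy())
        b.mask_left = BinaryMask(m2.astype(np.uint8), b.image.affine.copy())
        atlas = build_fuzzy_atlas([a, b])
        assert atlas.fuzzy_left.data[10, 10, 10] == pytest.approx(0.5)
        assert atlas.fuzzy_left.data[20, 20, 20] == pytest.approx(0.5)

    def test_permutation_invariance(self, cohort6):
        a = build_fuzzy_atlas(cohort6[:4])
        b = build_fuzzy_atlas(list(reversed(cohort6[:4])))
        assert np.allclose(a.template_image.data, b.template_image.data)
        assert np.allclose(a.fuzzy_right.data, b.fuzzy_right.data)

    def test_cohort_fuzzy_peak_inside_landmark_slab(self, cohort20):
        atlas = build_fuzzy_atlas(cohort20)
        # Overlap of jittered masks keeps the fuzzy peak high near the
        # nominal LC location.
        assert atlas.fuzzy_left.data.max() >= 0.5
        assert atlas.fuzzy_left.data.min() >= 0.0
        assert atlas.fuzzy_left.data.max() <= 1.0

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            build_fuzzy_atlas([])


@pytest.fixture(scope="module")
def normalized_pair(cohort6):
    fixed = normalize_std(cohort6[0].image)
    moving = normalize_std(cohort6[1].image)
    return moving, fixed


FAST = DemonsParams(iterations=10, levels=2)


class TestDemons:
    def test_self_registration_is_identity(self, normalized_pair):
        _, fixed = normalized_pair
        fld = demons_register(fixed, fixed, FAST)
        assert np.abs(fld.displacement_voxels()).max() < 0.1

    def test_known_translation_recovered(self, cohort6):
        img = normalize_std(cohort6[2].image)
        moving = Volume(np.roll(img.data, (2, 0, 0), axis=(0, 1, 2)),
                        img.affine)
        fld = demons_register(moving, img)
        fg = cohort6[2].image.data > 0
        mean_disp = fld.displacement_voxels()[fg].mean(axis=0)
        assert mean_disp[0] == pytest.approx(2.0, rel=0.25)

    def test_msd_never_increases_under_defaults(self, normalized_pair):
        moving, fixed = normalized_pair
        fld = demons_register(moving, fixed, FAST)
        assert fld.converged
        for msd0, msd1 in fld.msd_trace:
            assert msd1 <= msd0 + 1e-12

    def test_jacobian_stays_positive(self, normalized_pair):
        moving, fixed = normalized_pair
        fld = demons_register(moving, fixed, FAST)
        assert fld.jacobian_positive_fraction() >= 0.99

    def test_warp_preserves_soft_mask_range(self, cohort6, normalized_pair):
        moving, fixed = normalized_pair
        fld = demons_register(moving, fixed, FAST)
        warped = warp_volume(
            Volume(cohort6[1].mask_left.data.astype(float),
                   cohort6[1].image.affine), fld)
        assert warped.data.min() >= -1e-9
        assert warped.data.max() <= 1.0 + 1e-9

    def test_grid_mismatch_rejected(self):
        a = make_volume(np.zeros((8, 8, 8)))
        b = make_volume(np.zeros((9, 8, 8)))
        with pytest.raises(ValueError):
            demons_register(a, b)

    def test_cross_check_against_simpleitk_demons(self, cohort6):
        # Independent oracle: SimpleITK's demons on the same translated
        # pair should recover a comparable mean displacement.
        sitk = pytest.importorskip("SimpleITK")
        img = normalize_std(cohort6[3].image)
        moving = Volume(np.roll(img.data, (2, 0, 0), axis=(0, 1, 2)),
                        img.affine)
        ours = demons_register(moving, img)
        fg = cohort6[3].image.data > 0
        ours_mean = ours.displacement_voxels()[fg].mean(axis=0)[0]

        f = sitk.GetImageFromArray(np.ascontiguousarray(
            img.data.T.astype(np.float32)))
        m = sitk.GetImageFromArray(np.ascontiguousarray(
            moving.data.T.astype(np.float32)))
        dem = sitk.DiffeomorphicDemonsRegistrationFilter()
        dem.SetNumberOfIterations(60)
        dem.SetStandardDeviations(1.5)
        fld = dem.Execute(f, m)
        arr = sitk.GetArrayFromImage(fld)  # (z, y, x, 3) with xyz order
        theirs_mean = arr[..., 0].T[fg].mean()
        assert ours_mean == pytest.approx(2.0, rel=0.25)
        assert theirs_mean == pytest.approx(ours_mean, abs=1.0)


class TestApplyAtlas:
    def test_template_as_test_recovers_binarized_fuzzy(self, cohort6):
        atlas = build_fuzzy_atlas(cohort6[:4])
        left, right, info = apply_atlas(
            atlas, atlas.template_image,
            DemonsParams(iterations=5, levels=1), normalize=False)
        ref_l = binarize_lcc(atlas.fuzzy_left, 0.5)
        assert dice(left, ref_l) >= 0.95
        assert info["registration_converged"]

    def test_shifted_phantom_recovered(self, cohort6):
        # Machinery check: register to a rigidly shifted subject and
        # propagate; the warped mask must land on the shifted truth region.
        atlas = build_fuzzy_atlas(cohort6[:5])
        case = cohort6[0]
        shifted = Volume(np.roll(case.image.data, (2, 1, 0), axis=(0, 1, 2)),
                         case.image.affine)
        left, right, info = apply_atlas(atlas, shifted)
        truth = BinaryMask(
            np.roll(case.mask_left.data, (2, 1, 0), axis=(0, 1, 2)),
            case.image.affine.copy())
        assert dice(left, truth) >= 0.4

    def test_empty_threshold_result_flagged(self, cohort6):
        atlas = build_fuzzy_atlas(cohort6[:4])
        # An unmatchable test image: pure noise kills the fuzzy overlap.
        rng = np.random.default_rng(0)
        noise = Volume(rng.random(atlas.template_image.shape) + 0.1,
                       atlas.template_image.affine)
        left, right, info = apply_atlas(
            atlas, noise, DemonsParams(iterations=3, levels=1),
            threshold=0.99)
        if left.data.sum() == 0:
            assert info["left_empty"]


class TestAtlasSegmenter:
    def test_loocv_compatible_interface(self, cohort6):
        est = AtlasSegmenter(side="left", iterations=8, levels=2)
        est.fit(cohort6[:3])
        soft = est.predict(cohort6[3].image)
        assert isinstance(soft, SoftMask)
        assert hasattr(est, "failure_flag_")
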