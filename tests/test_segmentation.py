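import numpy as np
import pytest

from gestaliver import phantoms, segmentation
from gestaliver.grids import SAT, VAT, MUSCLE, ORGAN, ImageVolume
from gestaliver.segmentation import SegmentationConfig, dice

from conftest import small_spec


def exact_cfg(threshold=160.0):
    """Absolute-threshold config with no denoising, for exactness tests."""
    return SegmentationConfig(adipose_threshold=threshold, denoise="none", min_component_voxels=0)


class TestCorrectBiasField:
    def test_zero_bias_near_identity(self, plain_small_phantom):
        ph = plain_small_phantom
        corrected, field = segmentation.correct_bias_field(ph.image, body_mask=ph.body_mask)
        rel = np.abs(corrected.data - ph.image.data) / np.maximum(np.abs(ph.image.data), 1e-9)
        assert rel[ph.body_mask].mean() < 0.01

    def test_reduces_within_sat_cv_under_bias(self):
        ph = phantoms.make_abdomen_phantom(small_spec(bias_amplitude=0.30, seed=6))
        sat = ph.truth.labels == SAT
        corrected, _ = segmentation.correct_bias_field(ph.image, body_mask=ph.body_mask)
        cv_before = ph.image.data[sat].std() / ph.image.data[sat].mean()
        cv_after = corrected.data[sat].std() / corrected.data[sat].mean()
        assert cv_after < cv_before

    def test_reduces_cv_with_noise_and_bias(self, noisy_small_phantom):
        ph = noisy_small_phantom
        sat = ph.truth.labels == SAT
        corrected, _ = segmentation.correct_bias_field(ph.image, body_mask=ph.body_mask)
        cv_before = ph.image.data[sat].std() / ph.image.data[sat].mean()
        cv_after = corrected.data[sat].std() / corrected.data[sat].mean()
        assert cv_after < cv_before

    def test_constant_image_identity(self):
        vol = ImageVolume(np.full((20, 20, 4), 7.0), (2.0, 2.0, 6.0))
        corrected, field = segmentation.correct_bias_field(vol)
        np.testing.assert_array_equal(corrected.data, vol.data)
        np.testing.assert_array_equal(field.data, 1.0)

    def test_field_is_positive(self, noisy_small_phantom):
        _, field = segmentation.correct_bias_field(
            noisy_small_phantom.image, body_mask=noisy_small_phantom.body_mask
        )
        assert (field.data > 0).all()


class TestComputeBodyMask:
    def test_recovers_phantom_body(self, noisy_small_phantom):
        ph = noisy_small_phantom
        body = segmentation.compute_body_mask(ph.image)
        assert dice(body, ph.body_mask) > 0.98
        muscle = ph.truth.labels == MUSCLE
        assert (body & muscle).sum() / muscle.sum() > 0.95

    def test_constant_volume_empty(self):
        vol = ImageVolume(np.zeros((10, 10, 3)), (2.0, 2.0, 6.0))
        assert not segmentation.compute_body_mask(vol).any()


class TestThresholdAdipose:
    def test_noise_free_exact_equality(self, plain_small_phantom):
        ph = plain_small_phantom
        mask = segmentation.threshold_adipose(ph.image, ph.body_mask, exact_cfg(160.0))
        truth = (ph.truth.labels == SAT) | (ph.truth.labels == VAT)
        np.testing.assert_array_equal(mask, truth)

    def test_noisy_default_dice(self, noisy_small_phantom):
        ph = noisy_small_phantom
        corrected, _ = segmentation.correct_bias_field(ph.image, body_mask=ph.body_mask)
        mask = segmentation.threshold_adipose(corrected, ph.body_mask)
        mask = segmentation.apply_exclusion_masks(mask, ph.exclusion.uterus, ph.exclusion.liver)
        truth = (ph.truth.labels == SAT) | (ph.truth.labels == VAT)
        assert dice(mask, truth) >= 0.95

    def test_all_excluding_threshold_warns_empty(self, plain_small_phantom):
        ph = plain_small_phantom
        with pytest.warns(UserWarning, match="excluded all"):
            mask = segmentation.threshold_adipose(ph.image, ph.body_mask, exact_cfg(1e9))
        assert not mask.any()

    def test_constant_body_empty_with_warning(self):
        vol = ImageVolume(np.full((20, 20, 4), 5.0), (2.0, 2.0, 6.0))
        body = np.ones(vol.shape, dtype=bool)
        with pytest.warns(UserWarning):
            mask = segmentation.threshold_adipose(vol, body)
        assert not mask.any()

    def test_empty_body_mask_rejected(self, plain_small_phantom):
        with pytest.raises(ValueError, match="body mask"):
            segmentation.threshold_adipose(
                plain_small_phantom.image, np.zeros(plain_small_phantom.image.shape, bool)
            )


class TestSegmentMuscle:
    def test_fully_seeded_noise_free(self, plain_small_phantom):
        ph = plain_small_phantom
        seeds = phantoms.make_seed_labels(ph.truth, range(ph.truth.shape[2]), erosion_radius=0)
        muscle = segmentation.segment_muscle(ph.image, seeds, body_mask=ph.body_mask)
        assert dice(muscle, ph.truth.labels == MUSCLE) >= 0.99

    def test_sparse_seeding(self, noisy_small_phantom):
        # 4 seeded slices of 12 emulates the sparse manual label map
        ph = noisy_small_phantom
        corrected, _ = segmentation.correct_bias_field(ph.image, body_mask=ph.body_mask)
        seeds = phantoms.make_seed_labels(ph.truth, [1, 4, 7, 10])
        muscle = segmentation.segment_muscle(corrected, seeds, body_mask=ph.body_mask)
        assert dice(muscle, ph.truth.labels == MUSCLE) >= 0.85

    def test_no_muscle_seeds_rejected(self, plain_small_phantom):
        ph = plain_small_phantom
        seeds = phantoms.make_seed_labels(ph.truth, [5])
        seeds.labels[seeds.labels == MUSCLE] = 0
        with pytest.raises(ValueError, match="muscle seeds"):
            segmentation.segment_muscle(ph.image, seeds, body_mask=ph.body_mask)

    def test_misplaced_seeds_exclude_sat(self, plain_small_phantom):
        # muscle-coded seeds dropped inside the organ: the catchment stays
        # interior and never claims the SAT ring
        ph = plain_small_phantom
        seeds_arr = np.zeros(ph.truth.shape, dtype=np.int16)
        organ_core = ph.truth.labels == ORGAN
        idx = np.argwhere(organ_core)[::50]
        seeds_arr[tuple(idx.T)] = MUSCLE
        seeds = phantoms.make_seed_labels(ph.truth, [0], erosion_radius=0)
        seeds.labels[:] = seeds_arr
        adipose = (ph.truth.labels == SAT) | (ph.truth.labels == VAT)
        muscle = segmentation.segment_muscle(
            ph.image, seeds, body_mask=ph.body_mask, adipose_mask=adipose
        )
        assert not (muscle & (ph.truth.labels == SAT)).any()

    def test_disjoint_from_adipose_mask(self, noisy_small_phantom):
        ph = noisy_small_phantom
        seeds = phantoms.make_seed_labels(ph.truth, [1, 4, 7, 10])
        adipose = (ph.truth.labels == SAT) | (ph.truth.labels == VAT)
        muscle = segmentation.segment_muscle(
            ph.image, seeds, body_mask=ph.body_mask, adipose_mask=adipose
        )
        assert not (muscle & adipose).any()


class TestSegmentSAT:
    def test_noise_free_dice(self, plain_small_phantom):
        ph = plain_small_phantom
        adipose = segmentation.threshold_adipose(ph.image, ph.body_mask, exact_cfg(160.0))
        sat = segmentation.segment_sat(adipose, ph.body_mask)
        assert dice(sat, ph.truth.labels == SAT) >= 0.95

    def test_zero_vat_sat_equals_total(self):
        spec = small_spec(include_liver=False, include_uterus=False, seed=2)
        spec.vat_blob_count = 0
        ph = phantoms.make_abdomen_phantom(spec)
        adipose = segmentation.threshold_adipose(ph.image, ph.body_mask, exact_cfg(160.0))
        sat = segmentation.segment_sat(adipose, ph.body_mask)
        np.testing.assert_array_equal(sat, adipose)

    def test_empty_adipose_gives_empty_sat(self, plain_small_phantom):
        ph = plain_small_phantom
        empty = np.zeros(ph.image.shape, dtype=bool)
        assert not segmentation.segment_sat(empty, ph.body_mask).any()

    def test_sat_subset_of_adipose(self, noisy_small_phantom):
        ph = noisy_small_phantom
        corrected, _ = segmentation.correct_bias_field(ph.image, body_mask=ph.body_mask)
        adipose = segmentation.threshold_adipose(corrected, ph.body_mask)
        sat = segmentation.segment_sat(adipose, ph.body_mask)
        assert not (sat & ~adipose).any()

    def test_adipose_outside_body_rejected(self, plain_small_phantom):
        ph = plain_small_phantom
        bad = np.ones(ph.image.shape, dtype=bool)
        with pytest.raises(ValueError, match="contained"):
            segmentation.segment_sat(bad, ph.body_mask)


class TestVATBySubtraction:
    def test_sat_equals_total_gives_empty(self):
        total = np.zeros((5, 5, 2), bool)
        total[1:4, 1:4, :] = True
        assert not segmentation.vat_by_subtraction(total, total.copy()).any()

    def test_set_arithmetic(self):
        total = np.zeros((10, 10, 1), bool)
        total.ravel()[:100] = True
        sat = np.zeros_like(total)
        sat.ravel()[:40] = True
        vat = segmentation.vat_by_subtraction(total, sat)
        assert vat.sum() == 60
        assert not (vat & sat).any()
        np.testing.assert_array_equal(vat | sat, total)

    def test_violating_subset_rejected(self):
        total = np.zeros((4, 4, 1), bool)
        sat = np.ones_like(total)
        with pytest.raises(ValueError, match="subset"):
            segmentation.vat_by_subtraction(total, sat)


class TestExclusionMasks:
    def test_empty_exclusions_identity(self, plain_small_phantom):
        ph = plain_small_phantom
        mask = ph.truth.labels == VAT
        empty = np.zeros_like(mask)
        np.testing.assert_array_equal(
            segmentation.apply_exclusion_masks(mask, empty, empty), mask
        )

    def test_full_exclusion_empties(self):
        mask = np.ones((6, 6, 2), bool)
        assert not segmentation.apply_exclusion_masks(mask, mask, mask).any()

    def test_bright_uterus_false_positives_removed(self, clean_small_phantom):
        # the bright uterus region thresholds as adipose; exclusion restores
        # the truth-level false-positive count
        ph = clean_small_phantom
        adipose = segmentation.threshold_adipose(ph.image, ph.body_mask, exact_cfg(150.0))
        truth = (ph.truth.labels == SAT) | (ph.truth.labels == VAT)
        fp_before = int((adipose & ~truth).sum())
        assert fp_before > 0
        cleaned = segmentation.apply_exclusion_masks(adipose, ph.exclusion.uterus, ph.exclusion.liver)
        fp_after = int((cleaned & ~truth).sum())
        assert fp_after == 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            segmentation.apply_exclusion_masks(
                np.ones((4, 4, 2), bool), np.ones((5, 4, 2), bool), np.ones((4, 4, 2), bool)
            )


class TestBoundAnalysisRegion:
    def test_full_span_identity(self, plain_small_phantom):
        ph = plain_small_phantom
        out = segmentation.bound_analysis_region(ph.image, 0, ph.image.shape[2])
        np.testing.assert_array_equal(out.data, ph.image.data)

    def test_half_crop_halves_counts_for_uniform_phantom(self):
        spec = small_spec(axial_taper=0.0, seed=2, include_liver=False, include_uterus=False)
        ph = phantoms.make_abdomen_phantom(spec)
        sat = ph.truth.labels == SAT
        nz = sat.shape[2]
        cropped = segmentation.bound_analysis_region(sat, 0, nz // 2)
        assert cropped.sum() * 2 == sat.sum()

    def test_truth_inside_bounds_unchanged(self, plain_small_phantom):
        ph = plain_small_phantom
        vat = ph.truth.labels == VAT
        ks = np.unique(np.argwhere(vat)[:, 2])
        cropped = segmentation.bound_analysis_region(vat, int(ks.min()), int(ks.max()) + 1)
        assert cropped.sum() == vat.sum()

    def test_reversed_indices_rejected(self, plain_small_phantom):
        with pytest.raises(ValueError):
            segmentation.bound_analysis_region(plain_small_phantom.image, 8, 3)


class TestPipelineInvariants:
    def test_small_noisy_end_to_end(self, noisy_small_phantom):
        ph = noisy_small_phantom
        seeds = phantoms.make_seed_labels(ph.truth, [1, 4, 7, 10])
        res = segmentation.run_pipeline(
            ph.image, seeds, ph.exclusion.uterus, ph.exclusion.liver
        )
        assert dice(res["sat"], ph.truth.labels == SAT) >= 0.95
        assert dice(res["vat"], ph.truth.labels == VAT) >= 0.90
        assert dice(res["muscle"], ph.truth.labels == MUSCLE) >= 0.85
        # class exclusivity and exact partition
        assert not (res["sat"] & res["vat"]).any()
        assert not (res["sat"] & res["muscle"]).any()
        assert not (res["vat"] & res["muscle"]).any()
        np.testing.assert_array_equal(res["sat"] | res["vat"], res["adipose"])

    def test_volume_invariant_under_axis_permutation(self, plain_small_phantom):
        from gestaliver.grids import mask_volume_cm3

        ph = plain_small_phantom
        mask = ph.truth.labels == SAT
        v1 = mask_volume_cm3(mask, ph.image.spacing)
        perm = (2, 0, 1)
        v2 = mask_volume_cm3(
            np.transpose(mask, perm), tuple(ph.image.spacing[i] for i in perm)
        )
        assert v1 == pytest.approx(v2)


class TestConfigValidation:
    def test_bad_iterations(self):
        with pytest.raises(ValueError):
            SegmentationConfig(bias_iterations=0).validate()

    def test_bad_threshold_rule(self):
        with pytest.raises(ValueError):
            SegmentationConfig(adipose_threshold="quantile").validate()

    def test_bad_denoise_mode(self):
        with pytest.raises(ValueError):
            SegmentationConfig(denoise="wavelet").validate()
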