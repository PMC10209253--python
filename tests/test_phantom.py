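import numpy as np
import pytest

from osteoseg import phantom
from osteoseg.core import ParameterError, Units
from tests.conftest import run_pipeline


class TestSpecValidation:
    def test_lesion_outside_grid_rejected(self):
        spec = phantom.PhantomSpec()
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        spec.lesions = [phantom.Lesion(centre=(300.0, 60.0, 40.0),
                                       radius_mm=5.0, suv=4.0,
                                       inside_bone=False)]
        with pytest.raises(ParameterError, match="outside the phantom grid"):
            spec.validate()

    def test_inside_bone_flag_enforced(self):
        spec = phantom.PhantomSpec()
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        spec.lesions = [phantom.Lesion(centre=(130.0, 120.0, 60.0),
                                       radius_mm=5.0, suv=4.0,
                                       inside_bone=True)]
        with pytest.raises(ParameterError, match="inside-bone"):
            spec.validate()

    def test_nonpositive_radius_rejected(self):
        spec = phantom.PhantomSpec()
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        spec.lesions = [phantom.Lesion(centre=(87.0, 60.0, 40.0),
                                       radius_mm=0.0, suv=4.0,
                                       inside_bone=False)]
        with pytest.raises(ParameterError):
            spec.validate()


class TestGeneration:
    def test_zero_lesions(self):
        spec = phantom.PhantomSpec(seed=1)
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        result = phantom.generate_phantom(spec)
        assert (result.truth_labels.data == 0).all()
        assert result.truth_stats == []
        assert result.suv.data.max() == spec.background_suv

    def test_fixed_seed_is_bit_reproducible(self):
        spec_a = phantom.preset_spec("oligo", seed=42, noise_suv=0.2,
                                     noise_hu=20.0)
        spec_b = phantom.preset_spec("oligo", seed=42, noise_suv=0.2,
                                     noise_hu=20.0)
        a = phantom.generate_phantom(spec_a)
        b = phantom.generate_phantom(spec_b)
        assert np.array_equal(a.ct.data, b.ct.data)
        assert np.array_equal(a.pet.data, b.pet.data)
        assert np.array_equal(a.truth_labels.data, b.truth_labels.data)

    def test_different_seed_changes_noise(self):
        a = phantom.generate_phantom(
            phantom.preset_spec("oligo", seed=1, noise_suv=0.2))
        b = phantom.generate_phantom(
            phantom.preset_spec("oligo", seed=2, noise_suv=0.2))
        assert not np.array_equal(a.pet.data, b.pet.data)

    def test_sphere_volume_within_voxelisation_bound(self):
        spec = phantom.PhantomSpec(seed=0)
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        radius = 8.0
        spec.lesions = [phantom.Lesion(centre=(87.0, 60.0, 60.0),
                                       radius_mm=radius, suv=5.0)]
        result = phantom.generate_phantom(spec)
        analytic_ml = 4.0 / 3.0 * np.pi * radius ** 3 / 1000.0
        assert result.truth_stats[0].volume_ml == pytest.approx(
            analytic_ml, rel=0.15)

    def test_ct_hu_levels(self, oligo_phantom):
        data = oligo_phantom.ct.data
        assert data.min() == pytest.approx(-1000.0)
        assert (data == 700.0).any()     # cortical shell
        assert (data == 50.0).any()      # marrow
        assert (data == 40.0).any()      # soft tissue

    def test_suv_recovered_through_conversion(self, oligo_phantom):
        from osteoseg.io_dicom import to_suv_map
        suv = to_suv_map(oligo_phantom.pet, oligo_phantom.factors)
        # quantisation error is far below one thousandth of an SUV
        np.testing.assert_allclose(suv.data, oligo_phantom.suv.data,
                                   atol=1e-3)

    def test_units(self, oligo_phantom):
        assert oligo_phantom.ct.units == Units.HU
        assert oligo_phantom.pet.units == Units.BQML
        assert oligo_phantom.suv.units == Units.SUV_BW
        assert oligo_phantom.truth_labels.units == Units.LABEL


class TestPipelineRoundTrip:
    def test_noise_free_recovery_is_exact(self, oligo_phantom):
        products = run_pipeline(oligo_phantom, suv_th=3.0)
        assert products["labels"].data.max() == 3
        # with noise off and plateaus above threshold the auto mask equals
        # the truth mask within the bone domain
        auto = products["labels"].data > 0
        truth = oligo_phantom.truth_labels.data > 0
        assert np.array_equal(auto, truth & products["bone"].data)
        assert (auto & ~truth).sum() == 0

    def test_extraosseous_organs_never_survive_masking(self, oligo_phantom):
        products = run_pipeline(oligo_phantom, suv_th=3.0)
        organ_spec = phantom._default_organs()
        suv = products["suv"]
        labels = products["labels"]
        for organ in organ_spec:
            idx = tuple(int(round(c / s)) for c, s in
                        zip(organ.centre, suv.spacing))
            assert suv.data[idx] == pytest.approx(organ.suv, abs=0.01)
            assert labels.data[idx] == 0

    def test_noise_robustness_preserves_count(self):
        quiet = phantom.generate_phantom(
            phantom.preset_spec("widespread", seed=3))
        noisy = phantom.generate_phantom(
            phantom.preset_spec("widespread", seed=3, noise_suv=0.1))
        for result in (quiet, noisy):
            products = run_pipeline(result, suv_th=3.0)
            assert products["labels"].data.max() == 7


class TestRandomCohort:
    def test_cohort_is_deterministic(self):
        a = phantom.random_cohort(3, seed=9)
        b = phantom.random_cohort(3, seed=9)
        assert [s.lesions for s in a] == [s.lesions for s in b]

    def test_cohort_lesions_inside_bone(self):
        for spec in phantom.random_cohort(4, seed=17):
            for lesion in spec.lesions:
                assert any(b.contains_sphere(lesion.centre, lesion.radius_mm)
                           for b in spec.skeleton)

    def test_invalid_size_rejected(self):
        with pytest.raises(ParameterError):
            phantom.random_cohort(0)
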