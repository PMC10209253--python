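import numpy as np
import pytest

from osteoseg import bone_mask as bm
from osteoseg import io_dicom, lesion, phantom, resample
from osteoseg.core import Units, VolumeImage


@pytest.fixture(scope="session")
def oligo_phantom():
    return phantom.generate_phantom(phantom.preset_spec("oligo", seed=7))


@pytest.fixture(scope="session")
def widespread_phantom():
    return phantom.generate_phantom(
        phantom.preset_spec("widespread", seed=11, noise_suv=0.1))


@pytest.fixture(scope="session")
def oligo_dicom_dir(tmp_path_factory, oligo_phantom):
    out = tmp_path_factory.mktemp("oligo_dicom")
    phantom.write_phantom_dicom(oligo_phantom, out)
    return out


def run_pipeline(result, suv_th=3.0, hu_th=110.0):
    """Run resample → bone mask → lesion stages on a phantom result."""
    suv = io_dicom.to_suv_map(result.pet, result.factors)
    ct_on_pet = resample.resample_ct_to_pet_grid(result.ct, suv)
    bone = bm.segment_bone(ct_on_pet, hu_th)
    masked = bm.apply_bone_mask(suv, bone)
    labels = lesion.segment_lesions(masked, suv_th)
    stats = lesion.quantify_lesions(labels, suv)
    return {"suv": suv, "bone": bone, "labels": labels, "stats": stats}


@pytest.fixture
def small_volume():
    rng = np.random.default_rng(0)
    data = rng.uniform(0, 10, size=(8, 9, 10))
    return VolumeImage(data, (2.0, 2.0, 3.0), (0.0, 0.0, 0.0), Units.SUV_BW)
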