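import numpy as np
import pytest

from strokeflow.grid import LabelVolume, VolumeGrid
from strokeflow.phantom import PhantomSpec, generate_study


@pytest.fixture(scope="session")
def ref_study():
    """The paper-matched MCAO scenario at the default study size (SPECT only)."""
    spec = PhantomSpec(seed=1, include_mri=False)
    return generate_study(spec, "reference_mcao")


@pytest.fixture(scope="session")
def zero_noise_study():
    """Noise-free reference scenario: the analysis must recover the design exactly."""
    spec = PhantomSpec(seed=3, noise_sd=0.0, include_mri=False,
                       timepoints_days=(0, 7))
    return generate_study(spec, "reference_mcao")


def make_hemisphere_labels(shape=(20, 16, 12), voxel_size_mm=0.5,
                           ventricle_box=None):
    """Minimal label volume: left/right split at the x midline, one region per side."""
    region = np.ones(shape, dtype=np.int16)
    hemi = np.full(shape, LabelVolume.HEMI_RIGHT, dtype=np.int16)
    hemi[: shape[0] // 2] = LabelVolume.HEMI_LEFT
    vent = np.zeros(shape, dtype=bool)
    if ventricle_box is not None:
        vent[ventricle_box] = True
        region[ventricle_box] = 0
    return LabelVolume(region_ids=region, hemisphere_ids=hemi,
                       ventricle_mask=vent,
                       voxel_size_mm=(voxel_size_mm,) * 3,
                       origin_mm=(0.0, 0.0, 0.0))


def make_volume(values, voxel_size_mm=0.5, modality="SPECT"):
    return VolumeGrid(values=values, voxel_size_mm=(voxel_size_mm,) * 3,
                      origin_mm=(0.0, 0.0, 0.0), modality=modality)
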