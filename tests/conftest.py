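import numpy as np
import pytest

from glymmark import alps
from glymmark.synthetic import PhantomSpec, generate_dwi_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free phantom on a coarse 4 mm grid with its full-volume fit."""
    spec = PhantomSpec(grid_shape=(45, 54, 45), voxel_size=4.0, noise_sd=0.0, seed=7)
    data = generate_dwi_phantom(spec)
    return spec, data


@pytest.fixture(scope="session")
def fitted_small_phantom(small_phantom):
    spec, data = small_phantom
    tv = alps.fit_diffusion_tensor(
        data.dwi, data.bvals, data.bvecs, voxel_size=spec.voxel_size
    )
    return spec, data, tv


def roi_union_mask(grid_shape, voxel_size):
    rois = alps.default_rois(grid_shape, voxel_size)
    mask = np.zeros(grid_shape, dtype=bool)
    for m in alps.roi_masks(rois, grid_shape, voxel_size).values():
        mask |= m
    return mask
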