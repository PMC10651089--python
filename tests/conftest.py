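import numpy as np
import pytest

from psfqc.stack_io import ImageStack, VoxelCalibration
from psfqc.synthetic_psf import SyntheticSpec, render_noise_free


def gaussian_blob_stack(
    shape=(21, 48, 48),
    centers=((10, 24, 24),),
    sigma_xy=2.0,
    sigma_z=2.0,
    amplitude=1000.0,
    background=10.0,
    calibration=VoxelCalibration(),
):
    """Direct analytic render of isotropic-lateral Gaussian blobs in pixel
    units; independent of the synthetic_psf module."""
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    data = np.full(shape, float(background))
    for cz, cy, cx in centers:
        data += amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_xy**2)
            - (zz - cz) ** 2 / (2 * sigma_z**2)
        )
    return ImageStack(data, calibration=calibration, source_name="blob")


@pytest.fixture
def single_blob():
    return gaussian_blob_stack()


@pytest.fixture
def noise_free_model_stack():
    """The model spot at 40 nm lateral sampling, no noise."""
    return render_noise_free(SyntheticSpec(A=1000, dx=40.0, seed=None))
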