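import numpy as np
import pytest

from octskin import PhantomParams, VoxelGeometry, render_phantom


@pytest.fixture(scope="session")
def tiny_geometry():
    """A small grid with the acquisition depth pitch (4.6875 um/voxel)."""
    return VoxelGeometry(96, 64, 48, extent_z_mm=0.45, extent_y_mm=0.375,
                         extent_x_mm=0.28125)


@pytest.fixture(scope="session")
def tiny_params(tiny_geometry):
    """Phantom parameters scaled so the default layers fit a 96-voxel depth."""
    return PhantomParams(
        geometry=tiny_geometry,
        gap_depth_vox=8.0,
        layer_thickness_um={2: 20.0, 3: 80.0, 4: 70.0},
        undulation_amplitude_vox=2.0,
        undulation_period_vox=20.0,
        tilt_amplitude_vox=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_phantom(tiny_params):
    from dataclasses import replace

    return render_phantom(replace(tiny_params, speckle=False))


@pytest.fixture(scope="session")
def speckled_phantom(tiny_params):
    from dataclasses import replace

    return render_phantom(replace(tiny_params, speckle=True, speckle_shape=8.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
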