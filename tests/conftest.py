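import numpy as np
import pytest

from ssngrowth import NoduleMask, PhantomSpec, VoxelGrid, render_phantom


@pytest.fixture
def sphere_spec():
    """Noiseless hard-edged 5 mm-radius sphere at 1 mm spacing."""
    return PhantomSpec(
        voi_shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
        nodule_center=(16.0, 16.0, 16.0), nodule_radii=(5.0, 5.0, 5.0),
        nodule_mean_hu=-600.0, background_hu=-850.0,
        background_noise_sd=0.0, edge_softness=0.0, seed=7)


@pytest.fixture
def sphere_phantom(sphere_spec):
    return render_phantom(sphere_spec)


def make_box_mask(shape_zyx, box_zyx, spacing=(1.0, 1.0, 1.0), hu=-600.0):
    """Uniform-HU grid with a solid axis-aligned cuboid mask at the corner."""
    vals = np.full(shape_zyx, hu)
    m = np.zeros(shape_zyx, bool)
    m[2:2 + box_zyx[0], 2:2 + box_zyx[1], 2:2 + box_zyx[2]] = True
    return VoxelGrid(vals, spacing), NoduleMask(m, spacing)
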