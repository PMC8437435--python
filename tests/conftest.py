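import numpy as np
import pytest

from jmpkit import synthetic


@pytest.fixture(scope="session")
def monolayer_scene():
    """Quiet monolayer movie with three dynamic junction patches."""
    return synthetic.make_monolayer_scene(n_cells=6, patch_spec=3,
                                          bleach_rate=0.0, drift=(0.0, 0.0),
                                          noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def hemisphere_scene():
    """One r=5 um hemisphere on a sheet at 0.2 um isotropic voxels."""
    return synthetic.make_membrane_volume(
        [{"kind": "hemisphere", "center_yx_um": (12.0, 12.0),
          "radius_um": 5.0}],
        voxel_size_um=(0.2, 0.2, 0.2), shape=(48, 128, 128),
        noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def hemisphere_mesh(hemisphere_scene):
    """Raw (unsmoothed) marching-cubes surface of the hemisphere scene."""
    from jmpkit import surface
    mask = surface.compute_valid_mask(hemisphere_scene.volume)
    binary = surface.segment_membrane(hemisphere_scene.volume, mask)
    return surface.extract_surface(binary, hemisphere_scene.voxel_size_um)
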