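import numpy as np
import pytest

from mitomorph.synth import (
    GaussianLaw,
    SceneSpec2D,
    SceneSpec3D,
    make_cell_scene_2d,
    make_volume_series,
)


@pytest.fixture(scope="session")
def gaussian_scene():
    """A mid-size 2D scene from a gaussian radial law, shared across tests."""
    spec = SceneSpec2D(radial_law=GaussianLaw(65, 8), n_objects=500, seed=11)
    scene, truth = make_cell_scene_2d(spec)
    return spec, scene, truth


@pytest.fixture(scope="session")
def static_volume_scene():
    """A single-frame 3D scene of well-separated objects, shared across tests."""
    spec = SceneSpec3D(
        shape=(1, 48, 160, 160),
        voxel_size=(0.15, 0.15, 0.15),
        n_objects=15,
        volume_sd_um3=1.0,
        seed=21,
    )
    series, truth = make_volume_series(spec)
    return spec, series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
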