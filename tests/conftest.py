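import numpy as np
import pytest

from rbcdetect import RBCDetector, SceneParams, generate_scene, generate_scenes

#: Study conditions for detector experiments: small fields with a handful
#: of partly clustered cells.
DETECTOR_SCENE = SceneParams(
    image_height=64,
    image_width=64,
    n_cells=5,
    radius_range=(5.0, 9.0),
    eccentricity_range=(0.0, 0.3),
    overlap_fraction=0.2,
    noise_sigma=0.02,
    background_gradient=0.05,
    seed=0,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def detector_scenes():
    """A small training set of ground-truth scenes."""
    return generate_scenes(DETECTOR_SCENE, 30, seed=100)


@pytest.fixture(scope="session")
def trained_detector(detector_scenes):
    """A detector trained once per session on the small scene set."""
    return RBCDetector(random_state=0).fit(detector_scenes)


@pytest.fixture(scope="session")
def single_cell_scene():
    """One isolated cell on a clean-ish background."""
    params = SceneParams(
        image_height=64,
        image_width=64,
        n_cells=1,
        radius_range=(7.0, 7.0),
        eccentricity_range=(0.0, 0.0),
        overlap_fraction=0.0,
        noise_sigma=0.01,
        background_gradient=0.03,
        seed=42,
    )
    return generate_scene(params)
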