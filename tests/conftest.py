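import numpy as np
import pytest

from segclick import PriorNoise, SceneConfig, generate_scene, make_prior


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64 scene with three objects, one per tissue class."""
    return generate_scene(SceneConfig(height=64, width=64, seed=7))


@pytest.fixture(scope="session")
def clean_prior(small_scene):
    return make_prior(small_scene, PriorNoise.none())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
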