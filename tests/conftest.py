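import numpy as np
import pytest

from plaqseg3d.synthgen import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A quiet 48^3 scene with a handful of plaques, shared across tests."""
    return generate_scene(SceneConfig(shape=(48, 48, 48), n_plaques=4,
                                      size_class_mix=(0.5, 0.5, 0.0),
                                      noise_sd=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
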