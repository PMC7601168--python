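import numpy as np
import pytest

from fluortex.synth import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One 256-px synthetic scene with default statistics (no device)."""
    return generate_scene(SceneSpec(seed=3, size=256))


@pytest.fixture(scope="session")
def device_scene():
    """One 256-px scene with a planted device aperture."""
    return generate_scene(SceneSpec(seed=5, size=256, device_circle=(0.5, 0.5, 0.42)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
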