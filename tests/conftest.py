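import numpy as np
import pytest

from vesselseg.synthetic import ScribblePolicy, SyntheticSceneSpec, generate_scene, make_benchmark, sparsify_labels


@pytest.fixture(scope="session")
def scene():
    """One default synthetic scene (image, dense truth)."""
    return generate_scene(SyntheticSceneSpec(seed=7))


@pytest.fixture(scope="session")
def scribbled_scene(scene):
    image, dense = scene
    mask = sparsify_labels(dense, ScribblePolicy(), np.random.default_rng(7))
    return image, dense, mask


@pytest.fixture(scope="session")
def benchmark():
    """Small patch benchmark shared by training-related tests."""
    return make_benchmark(3, seed=11)
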