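import numpy as np
import pytest

import mooneygen as mg


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def nested_rects():
    """64x64 three-level nested-rectangle scene (values 60/120/180)."""
    return mg.make_fixture(mg.FixtureSpec("nested_rects", shape=(64, 64)))


@pytest.fixture
def bimodal():
    """Bimodal object-on-background scene, the pipeline's model input."""
    return mg.make_fixture(
        mg.FixtureSpec("bimodal", shape=(64, 64), seed=7,
                       params={"mu0": 40.0, "mu1": 200.0, "sd": 10.0})
    )


def random_edge_map(rng, shape=(16, 16), density=0.1):
    return rng.random(shape) < density
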