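import numpy as np
import pytest

from stokescope import NoiseModel, PhantomSpec, generate_phantom, simulate_acquisition


@pytest.fixture(scope="session")
def standard_scene():
    """The default phantom field: 3 granulocytes, 3 lymphocytes, 2 monocytes."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def noisy_stack(standard_scene):
    """Standard phantom acquired with 1%-of-full-scale Gaussian noise."""
    return simulate_acquisition(
        standard_scene, noise=NoiseModel(kind="gaussian", level=0.01), seed=11
    )


@pytest.fixture(scope="session")
def clean_stack(standard_scene):
    return simulate_acquisition(standard_scene, noise=NoiseModel.none())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
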