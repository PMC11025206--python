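import numpy as np
import pytest

from plexus.phantom import PhantomSpec, generate_phantom
from plexus.segment import segment_cp


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_sd=0.0)
    image, labels, truth = generate_phantom(spec)
    return spec, image, labels, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(seed=1)
    image, labels, truth = generate_phantom(spec)
    return spec, image, labels, truth


@pytest.fixture(scope="session")
def noisy_segmentation(noisy_phantom):
    _, image, labels, truth = noisy_phantom
    return segment_cp(image, labels), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
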