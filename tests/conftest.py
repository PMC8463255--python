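import numpy as np
import pytest

import rbfseg as rs


@pytest.fixture(scope="session")
def benchmark_phantom():
    """Default benchmark phantom (128x128, 3 classes) at a fixed seed."""
    spec = rs.benchmark_spec(seed=7)
    image, labels = rs.generate_phantom(spec)
    return spec, image, labels


@pytest.fixture(scope="session")
def trained_network(benchmark_phantom):
    """A closed-form-trained network plus its train/test pixel samples."""
    _, image, labels = benchmark_phantom
    train_set = rs.sample_pixels(labels, 100, seed=21, image=image)
    test_set = rs.sample_pixels(
        labels, 100, seed=22, exclude=train_set.coord_set,
        image=image, scaling=train_set.scaling,
    )
    network, log = rs.train(train_set, seed=23)
    return network, log, train_set, test_set


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
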