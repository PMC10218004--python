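import numpy as np
import pytest

from edgetrack.synth import (
    EventTrainSpec,
    SyntheticKernelSpec,
    generate_event_train,
    generate_synthetic_kernel,
)

FS = 400.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def kernel():
    return generate_synthetic_kernel(SyntheticKernelSpec(fs=FS))


@pytest.fixture(scope="session")
def regular_train():
    """One minute of regular-speech landmark statistics."""
    return generate_event_train(EventTrainSpec(5.7, 2.9, 60.0, seed=11))


@pytest.fixture(scope="session")
def slow_train():
    """Three minutes of slowed-speech landmark statistics."""
    return generate_event_train(EventTrainSpec(1.9, 1.0, 180.0, seed=12))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
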