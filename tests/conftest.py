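import numpy as np
import pytest

from groovebinder.sampling import SamplingConfig, sample_library


@pytest.fixture(scope="session")
def small_library():
    """Shared seeded library of accepted groove candidates."""
    lib, stats = sample_library(60, SamplingConfig(seed=11))
    return lib, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
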