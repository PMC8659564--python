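from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from emgkin.synthetic import SynthConfig, generate_dataset

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 subjects x 4 loads x 5 cycles, default noise and lags."""
    return generate_dataset(replace(SynthConfig(), n_subjects=3, seed=42))


@pytest.fixture(scope="session")
def tiny_recording(tiny_dataset):
    return tiny_dataset[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
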