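import numpy as np
import pytest

from myofuse.synthgen import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_config():
    """Short-duration study conditions for fast unit tests."""
    return SynthConfig(duration_s=8.0, seed=42)


@pytest.fixture
def default_config():
    return SynthConfig(seed=42)
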