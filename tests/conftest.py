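import numpy as np
import pytest

from vtsnn import NetworkSpec, build_uvtsnn, generate_synthetic


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest useful U-net: depth 1, base 8 channels (~5.8k weights)."""
    return build_uvtsnn(NetworkSpec(depth=1, base_channels=8), seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_synthetic(8, 28, 28, seed=5, eta=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
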