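import numpy as np
import pytest

from cleavekit import KineticParameters


@pytest.fixture
def equal_affinity_params() -> KineticParameters:
    """A realistic tag-removal reaction: 100 uM substrate, 0.5 uM protease,
    K_M = K_P = 10 uM, kcat = 1/min."""
    return KineticParameters(kcat=1.0, K_M=10.0, K_P=10.0, E0=0.5, S0=100.0)


@pytest.fixture
def times_2h() -> np.ndarray:
    return np.array([0.0, 5, 10, 15, 20, 30, 45, 60, 90, 120])
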