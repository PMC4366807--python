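import numpy as np
import pytest

from ircom import EvoParams, GameParams, IRParams


@pytest.fixture
def donor_game() -> GameParams:
    """Canonical Donor-game economics: b=4, c=1, eps=0.25, delta=4."""
    return GameParams(b=4.0, c=1.0, eps=0.25, delta=4.0)


@pytest.fixture
def ir_default() -> IRParams:
    return IRParams(theta=0.28, r=1.0)


@pytest.fixture
def evo_default() -> EvoParams:
    return EvoParams(N=100, beta=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
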