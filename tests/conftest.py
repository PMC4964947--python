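import numpy as np
import pytest
from hypothesis import settings

from mitopoisson.model import GrowthModel

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def ref_model() -> GrowthModel:
    """Reference field: 65 cells, gamma = 0.033/h (t_IMT ~ 21 h)."""
    return GrowthModel(n0=65, gamma=0.033)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
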