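import numpy as np
import pytest

from foldbind.equilibria import ThreeStateModel


@pytest.fixture
def study_model() -> ThreeStateModel:
    """Three-state constants of the study system: kd1=1.8 µM, k2=5."""
    return ThreeStateModel(kd1=1.8, k2=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
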