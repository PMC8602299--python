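import numpy as np
import pytest

from wristkin.chain import LimbModel


@pytest.fixture
def limb() -> LimbModel:
    """Reference limb: 30 cm arm + 25 cm forearm (55 cm full extension)."""
    return LimbModel(L_arm=30.0, L_fa=25.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
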