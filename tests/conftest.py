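import numpy as np
import pytest

from pfwalk import ContinuousParams

#: fitted human parameters: D (1/yr), V (1/yr), x0 = 1, unbounded death threshold
HUMAN = ContinuousParams(D=0.004, V=0.051, x0=1.0)
MEDIAN_SUPPLY = 3.23e5
THRESHOLD = 1000


@pytest.fixture
def human_params() -> ContinuousParams:
    return HUMAN


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
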