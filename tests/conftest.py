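import numpy as np
import pytest

from mhgs import HGSParams, RandomStream, SearchSpace


@pytest.fixture
def rng():
    return RandomStream(12345)


@pytest.fixture
def space10():
    return SearchSpace(10, -100.0, 100.0)


@pytest.fixture
def small_params():
    return HGSParams(n_agents=10, max_fe=600)
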