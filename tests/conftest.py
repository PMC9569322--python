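import numpy as np
import pytest
from hypothesis import settings

from memquench import SCENARIOS, get_scenario

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def stni_chol():
    return get_scenario("StnI_chol")


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def binding_rows():
    return [(k, v.binding) for k, v in SCENARIOS.items() if v.binding]


def exposure_rows():
    return [(k, v.exposure) for k, v in SCENARIOS.items() if v.exposure]


def depth_rows():
    return [(k, v.depth) for k, v in SCENARIOS.items() if v.depth]
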