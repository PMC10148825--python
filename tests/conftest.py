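import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promethee2 import paper_case_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_dm():
    return paper_case_study()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
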