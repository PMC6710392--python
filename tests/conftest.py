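import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tisim.task import ListSpec  # noqa: E402


@pytest.fixture
def list7() -> ListSpec:
    return ListSpec.of_size(7)


@pytest.fixture
def list5() -> ListSpec:
    return ListSpec.of_size(5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
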