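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


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """Pipeline configuration scaled for sub-second unit-test runs."""
    from mottle import MottleConfig

    return MottleConfig(flank_size=40, window=20, min_clipped=40, seed=0)


def random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
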