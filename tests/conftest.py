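import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
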