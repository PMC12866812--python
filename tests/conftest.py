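import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def image_bits():
    """16384-bit payload from a Rule-182 pattern image (structured data)."""
    from dnastore import fixtures

    return fixtures.flatten(fixtures.eca_matrix(182, 128, 128, init="center"))


@pytest.fixture(scope="session")
def random_bits_16384():
    """Seed-0 uniform random 16384-bit payload."""
    from dnastore import fixtures

    return fixtures.random_bits(16384, seed=0)


@pytest.fixture(scope="session")
def fuzz_payloads():
    """1000 random bit strings, lengths 1–2048, fixed seed."""
    rng = np.random.default_rng(12345)
    out = []
    for _ in range(1000):
        n = int(rng.integers(1, 2049))
        out.append("".join("01"[b] for b in rng.integers(0, 2, size=n)))
    return out
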