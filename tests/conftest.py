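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
    return np.random.default_rng(1234)


class StubRng:
    """Minimal deterministic stand-in for a numpy Generator in unit tests."""

    def __init__(self, poisson=0, integers=0, normal=0.0, random=0.5):
        self._poisson = poisson
        self._integers = integers
        self._normal = normal
        self._random = random

    def poisson(self, lam, size=None):
        return self._poisson if size is None else np.full(size, self._poisson)

    def integers(self, low, high=None, size=None):
        return self._integers if size is None else np.full(size, self._integers)

    def normal(self, loc=0.0, scale=1.0, size=None):
        if size is None:
            return self._normal
        return np.full(size, self._normal)

    def random(self, size=None):
        return self._random if size is None else np.full(size, self._random)

    def choice(self, n, size=None, replace=True, p=None):
        return 0


@pytest.fixture
def stub_rng_factory():
    return StubRng
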