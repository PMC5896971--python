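import numpy as np
import pytest
from hypothesis import settings

from labaudit import AuditPolicy, CostModel, WorldParams

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


class StubRNG:
    """Scripted random source for forcing specific model paths."""

    def __init__(self, uniforms=(), normals=()):
        self.uniforms = list(uniforms)
        self.normals = list(normals)

    def random(self):
        return self.uniforms.pop(0)

    def normal(self, loc=0.0, scale=1.0):
        return loc + scale * self.normals.pop(0)

    def integers(self, n):
        return 0

    def choice(self, n, size=1, replace=True):
        return np.arange(size)


@pytest.fixture
def world():
    return WorldParams()


@pytest.fixture
def policy():
    return AuditPolicy()


@pytest.fixture
def costs():
    return CostModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20180412)
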