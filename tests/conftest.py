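import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class ScriptedRNG:
    """Stand-in RNG returning a scripted sequence of uniform draws."""

    def __init__(self, values):
        self.values = list(values)
        self.consumed = 0

    def random(self):
        self.consumed += 1
        return self.values.pop(0)


@pytest.fixture
def scripted_rng():
    return ScriptedRNG
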