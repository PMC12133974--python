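import numpy as np
import pytest

from glct.fixtures import random_phase_type, random_predprey, random_seirs


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


@pytest.fixture
def random_ph(rng):
    def draw(**kwargs):
        return random_phase_type(rng, **kwargs)

    return draw


@pytest.fixture
def seirs_draw(rng):
    def draw(**kwargs):
        return random_seirs(rng, **kwargs)

    return draw


@pytest.fixture
def predprey_draw(rng):
    def draw(**kwargs):
        return random_predprey(rng, **kwargs)

    return draw
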