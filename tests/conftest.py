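import numpy as np
import pytest

from beliefgame import BeliefFunction, make_frame


@pytest.fixture
def frame1():
    return make_frame(1)


@pytest.fixture
def frame2():
    return make_frame(2)


def bf(frame, **masses):
    """Belief function from keyword masses, e.g. bf(frame, R1=0.4, I1=0.6)."""
    return BeliefFunction.from_dict(
        frame, {k.replace("_", "+"): v for k, v in masses.items()}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
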