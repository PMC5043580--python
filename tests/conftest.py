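import numpy as np
import pytest

from motifgrammar import BackgroundModel, PWM


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture
def pwm_a07():
    """Width-2 PWM with p(A)=0.7 at both positions (others 0.1)."""
    return PWM("a07", np.tile([0.7, 0.1, 0.1, 0.1], (2, 1)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pwm_probs(rng, width):
    return rng.dirichlet(np.ones(4), size=width)


@pytest.fixture
def random_pwms(rng):
    return [
        PWM(f"r{i}", random_pwm_probs(rng, int(rng.integers(4, 13))))
        for i in range(20)
    ]
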