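import numpy as np
import pytest

from regboot.io_formats import PWM


@pytest.fixture
def uniform_pwm():
    """Zero-information motif: every row equals the uniform background."""
    return PWM(probs=np.full((4, 4), 0.25))


@pytest.fixture
def acgt_pwm():
    """Near-deterministic 4-mer ACGT motif."""
    probs = np.full((4, 4), 0.01)
    for i in range(4):
        probs[i, i] = 0.97
    return PWM(probs=probs)


def make_informative_pwm(consensus: str, certainty: float = 0.97) -> PWM:
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(consensus), 4), (1 - certainty) / 3)
    for i, b in enumerate(consensus):
        probs[i, idx[b]] = certainty
    return PWM(probs=probs)
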