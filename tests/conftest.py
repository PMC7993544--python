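import numpy as np
import pytest

from condecomp import PulseSequence


@pytest.fixture(scope="session")
def phantom_seq() -> PulseSequence:
    """Pulsed-gradient timing of the vesicle-phantom protocol (δ/Δ = 6/53.8 ms)."""
    return PulseSequence(delta=6e-3, Delta=53.8e-3)


@pytest.fixture(scope="session")
def human_seq() -> PulseSequence:
    """Timing of the human protocol (δ/Δ = 21/33 ms)."""
    return PulseSequence(delta=21e-3, Delta=33e-3)


@pytest.fixture(scope="session")
def shells() -> np.ndarray:
    """The four-shell acquisition b = 1000, 2200, 3000, 3600 s/mm²."""
    return np.array([1000.0, 2200.0, 3000.0, 3600.0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
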