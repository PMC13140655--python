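import numpy as np
import pytest

from breathnet.synthetic import CouplingSpec, Edge
from breathnet.te import TEConfig


def stream(*key: int) -> np.random.Generator:
    """Deterministic generator on a substream disjoint from other keys.

    Using structured SeedSequence keys (rather than reusing small integers
    for both data and surrogate permutations) keeps the independent random
    streams a calibration test assumes actually independent.
    """
    return np.random.default_rng(np.random.SeedSequence(key))


@pytest.fixture
def te_config():
    return TEConfig()  # lag 5, quantile bins, 6 bins


@pytest.fixture
def single_link_spec():
    """One strong HR -> RF link at the analysis horizon (lags 4-5)."""
    return CouplingSpec(edges=(Edge("HR", "RF", 5, 0.8),
                               Edge("HR", "RF", 4, 0.8)))


@pytest.fixture
def uncoupled_spec():
    """Seven independent AR channels (all coupling strengths zero)."""
    return CouplingSpec(edges=())
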