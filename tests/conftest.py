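import numpy as np
import pytest

from quadtune import VirtualInstrument
from quadtune.instrument import ParameterDef


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_instrument():
    return VirtualInstrument(noise_cv=0.0)


@pytest.fixture
def noisy_instrument():
    return VirtualInstrument(seed=11)


def _make_two_param_instrument(interaction: bool, noise_cv: float = 0.0,
                               optimum=None, seed: int = 0) -> VirtualInstrument:
    """Small two-parameter plant for exhaustive-search oracles."""
    params = (ParameterDef("DP", 50.0, 200.0), ParameterDef("EP", 2.0, 15.0))
    return VirtualInstrument(
        params=params,
        optimum=optimum or {"DP": 163.03, "EP": 11.413},
        sigma={"DP": 30.0, "EP": 2.5},
        interaction=interaction,
        noise_cv=noise_cv,
        seed=seed,
    )


@pytest.fixture
def two_param_instrument():
    return _make_two_param_instrument
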