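import numpy as np
import pytest

from methylscreen.simulate import (
    TraceSimParams,
    amplicon_spec,
    simulate_reference_trace,
)


@pytest.fixture
def noiseless_params():
    return TraceSimParams(noise_sd=0.0)


@pytest.fixture
def spec(noiseless_params):
    return amplicon_spec(noiseless_params)


@pytest.fixture
def reference(noiseless_params):
    return simulate_reference_trace(noiseless_params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
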