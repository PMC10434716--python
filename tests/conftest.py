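import numpy as np
import pytest

import visfield as vf


@pytest.fixture(scope="session")
def params():
    """The calibrated shared parameter set."""
    return vf.default_params()


@pytest.fixture(scope="session")
def quiet_params(params):
    """Noise-free variant for deterministic checks."""
    from dataclasses import replace

    return replace(params, noise_slow_amp=0.0, noise_fast_amp=0.0)


@pytest.fixture(scope="session")
def grid():
    return vf.FieldGrid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
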