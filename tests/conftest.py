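import numpy as np
import pytest

from clampdyn.exchange import FastExchangeParams
from clampdyn import synthetic as syn


@pytest.fixture
def dispersive_params() -> FastExchangeParams:
    """A clearly dispersive parameter set (plateau R_ex/k_ex = 8 s⁻¹)."""
    return FastExchangeParams(r2_0=25.0, rex=8.0 * 1500.0, kex=1500.0)


@pytest.fixture
def noisefree_profile(dispersive_params):
    profile, truth = syn.gen_cpmg_profile(dispersive_params, noise_sd=0.0)
    return profile, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
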