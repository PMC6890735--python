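import numpy as np
import pytest

from lampsim import GrowthParams, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def growth():
    return GrowthParams()


@pytest.fixture
def small_params():
    """A downsized system for fast dynamical tests (same structure)."""
    return ModelParams(
        n_years=30, n_tributaries=6, larval_K=300, juvenile_K=1500,
        tfm_start_year=10, resistant_intro_year=15, dd_weight=50.0,
    )
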