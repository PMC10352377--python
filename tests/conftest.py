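import numpy as np
import pytest

from synthpool.simulate import austria_like, canada_like, simulate_country
from synthpool.synthesis import TuningConfig, fit_sequential, generate_replicates

NO_TUNE = TuningConfig(n_trials=0)


@pytest.fixture(scope="session")
def canada_small():
    return simulate_country(canada_like(3000), seed=11)


@pytest.fixture(scope="session")
def austria_small():
    return simulate_country(austria_like(1500), seed=12)


@pytest.fixture(scope="session")
def canada_20k():
    return simulate_country(canada_like(20_000), seed=13)


@pytest.fixture(scope="session")
def model_20k(canada_20k):
    """Sequential model fitted once at study scale, shared across fidelity tests."""
    return fit_sequential(canada_20k, config=NO_TUNE, seed=14)


@pytest.fixture(scope="session")
def replicates_20k(model_20k):
    return generate_replicates(model_20k, n=20_000, m=3, seed=15)
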