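import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aiblpka import BondFeatureVector, load_test_set_table
from aiblpka.synthetic import SeriesSpec, generate_series

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

IDEAL = BondFeatureVector(r_OH=0.99, r_CO=1.33, r_CC_double=1.37,
                          r_CC_single=1.44, r_CO_double=1.24)


@pytest.fixture(scope="session")
def test_table():
    return load_test_set_table()


@pytest.fixture
def ideal_lengths():
    return IDEAL


@pytest.fixture
def signal_series():
    """Series where only r_CO carries signal; the other bonds are noise."""
    def make(seed=0, n=49, noise_sd=0.3):
        spec = SeriesSpec(label="sig", n_compounds=n, noise_sd=noise_sd,
                          cross_correlations=np.eye(5), seed=seed)
        return generate_series(spec)
    return make
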