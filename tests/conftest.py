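import numpy as np
import pytest

import dyadsync as ds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    # small, fast cohort: 24 couples, 2-minute series, one shared structure
    return ds.GeneratorConfig(n_couples=24, series_length=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ds.generate_cohort(small_config)
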