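import numpy as np
import pytest

import aortanorm as an


@pytest.fixture(scope="session")
def chinese_spec():
    return an.default_specs(n=910)["chinese_like"]


@pytest.fixture(scope="session")
def italian_spec():
    return an.default_specs(n=910)["italian_like"]


@pytest.fixture(scope="session")
def chinese_cohort(chinese_spec):
    """A full-size synthetic Chinese-like cohort (n = 910, sigma = 0.11)."""
    return an.generate_population(chinese_spec, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 200-subject cohort for unit tests that only need structure."""
    spec = an.default_specs(n=200)["chinese_like"]
    return an.generate_population(spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
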