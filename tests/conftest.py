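import numpy as np
import pytest

from ribowalk.kinetics import RateProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_site_open():
    return RateProfile(epsilons=np.array([2.0, 3.0]), reinit_prob=0.0, alpha=10.0)


@pytest.fixture
def two_site_circular():
    return RateProfile(epsilons=np.array([2.0, 3.0]), reinit_prob=1.0, alpha=10.0)


@pytest.fixture
def random_open_profile(rng):
    return RateProfile(epsilons=rng.uniform(1.0, 10.0, 8), reinit_prob=0.0)


@pytest.fixture
def random_circular_profile(rng):
    return RateProfile(epsilons=rng.uniform(1.0, 10.0, 6), reinit_prob=1.0)
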