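import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lsafilter as lf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage() -> lf.Montage:
    """The shipped 120-channel 10-5 cap."""
    return lf.standard_105_montage(120)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def random_epochs(montage, rng) -> lf.EpochSet:
    """Unstructured random epochs on the full cap: 30 trials, 3 samples."""
    data = rng.normal(0.0, 5.0, size=(30, 120, 3))
    return lf.EpochSet(data, montage.labels, [0.0, 0.001, 0.002], 1000.0)


def make_epochs(data, labels, srate=1000.0) -> lf.EpochSet:
    data = np.asarray(data, dtype=float)
    times = np.arange(data.shape[2]) / srate
    return lf.EpochSet(data, labels, times, srate)
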