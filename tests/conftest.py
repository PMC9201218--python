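import numpy as np
import pytest

from bggreg.model import BGGComponent, BGGMixture, MonteCarloBank, SupportRegion


@pytest.fixture
def gaussian_component():
    """Shape-2 single-channel component on an effectively unbounded box."""
    return BGGComponent(
        mean=[10.0],
        scale=[3.0],
        shape=[2.0],
        support=SupportRegion([-np.inf], [np.inf]),
    )


@pytest.fixture
def two_channel_component():
    return BGGComponent(
        mean=[100.0, 150.0],
        scale=[10.0, 20.0],
        shape=[2.0, 2.0],
        support=SupportRegion.default(2),
    )


@pytest.fixture
def bank_factory():
    def make(component, count=10_000, seed=0):
        return MonteCarloBank.draw(component, count, seed)

    return make


def make_component(mean, scale, shape, lower=None, upper=None):
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    n = mean.size
    if lower is None:
        lower = np.full(n, -np.inf)
    if upper is None:
        upper = np.full(n, np.inf)
    return BGGComponent(mean=mean, scale=scale, shape=shape, support=SupportRegion(lower, upper))


def two_blob_data(n=2000, seed=0, mu1=(60.0, 60.0), mu2=(180.0, 180.0), s1=10.0, s2=15.0, w1=0.4):
    """Two spherical Gaussian blobs clipped into [0, 255]; handy EM fixture."""
    rng = np.random.default_rng(seed)
    n1 = int(round(w1 * n))
    a = rng.normal(mu1, s1, (n1, 2))
    b = rng.normal(mu2, s2, (n - n1, 2))
    return np.clip(np.vstack([a, b]), 0.0, 255.0)
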