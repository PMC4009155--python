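import numpy as np
import pytest
from hypothesis import settings

from spikefield import (
    CompositeKernelSpec,
    LFPWindow,
    MultichannelLFPWindow,
    MultiscaleSample,
    MultiunitSpikeWindow,
    SpikeWindow,
)

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def random_sample(
    rng: np.random.Generator,
    n_units: int = 3,
    n_channels: int = 2,
    T_s: float = 9.0,
    T_x: float = 20.0,
    mean_spikes: float = 1.5,
) -> MultiscaleSample:
    """A random multiscale window: Poisson spike counts at uniform times,
    Gaussian LFP samples."""
    units = []
    for _ in range(n_units):
        m = rng.poisson(mean_spikes)
        units.append(SpikeWindow(np.sort(rng.uniform(0, T_s, size=m)), T_s))
    chans = tuple(
        LFPWindow(rng.normal(0, 1, size=int(T_x)), 1.0) for _ in range(n_channels)
    )
    return MultiscaleSample(
        MultiunitSpikeWindow(tuple(units)), MultichannelLFPWindow(chans)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    """A fully resolved normalized product-kernel spec."""
    return CompositeKernelSpec(sigma_s=0.3, sigma_x=3.0, smoothing_width=9.0)


@pytest.fixture
def sample_factory(rng):
    def make(n=1, **kw):
        out = [random_sample(rng, **kw) for _ in range(n)]
        return out[0] if n == 1 else out

    return make
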