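import numpy as np
import pytest
from hypothesis import settings

from parafit import IrfSpec, TimingContext, gaussian_irf

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ctx64() -> TimingContext:
    return TimingContext(T=12.5, N=64)


@pytest.fixture(scope="session")
def irf64(ctx64) -> IrfSpec:
    return gaussian_irf(ctx64, t0=1.0, fwhm=0.1)
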