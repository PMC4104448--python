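import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flimfret import IRFSpec, TCSPCConfig, delta_irf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TAU_D = 2.65
TAU_F = 0.83


@pytest.fixture(scope="session")
def config() -> TCSPCConfig:
    """Default time base: 20 ps channels, 25 ns window, 24 ns analysis."""
    return TCSPCConfig()


@pytest.fixture(scope="session")
def gauss_irf() -> IRFSpec:
    """Default parametric IRF: Gaussian, fwhm 100 ps, centered at 0.5 ns."""
    return IRFSpec()


@pytest.fixture(scope="session")
def delta0(config) -> IRFSpec:
    """Instantaneous IRF in channel 0."""
    return delta_irf(config, 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
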