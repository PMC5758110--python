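import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def reference_truth():
    """The canonical synthetic flash response used across tests."""
    from primekin.synthetic_data import GroundTruth

    return GroundTruth(a_fast=150.0, tau_fast=0.020, a_slow=150.0,
                       tau_slow=0.150, sustained_rate=40.0)


@pytest.fixture
def flash_protocol():
    from primekin.synthetic_data import FlashProtocol

    return FlashProtocol(flash_time=0.5, pre_ca=500.0, post_ca=20.0, duration=6.0)


@pytest.fixture
def reference_params():
    from primekin.pool_model import PoolModelParams

    return PoolModelParams(
        depot=1000.0, k1=0.01, k_minus1=0.05, k2=0.1, k_minus2=0.05,
        gamma_fast=50.0, gamma_slow=1.0 / 0.15,
    )
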