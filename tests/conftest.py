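import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import entrocast as ec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_table():
    """Published ten-day Guangzhou comparison (actual + per-method forecasts)."""
    return ec.load_guangzhou_jan2015()


@pytest.fixture(scope="session")
def ar1_series():
    """Seeded AR(1) path, phi = 0.7, n = 2000, shifted positive."""
    return ec.simulate_arma(2000, phi=(0.7,), seed=7) + 50.0


@pytest.fixture
def small_series():
    """Short positive daily series for contract tests."""
    return ec.DailySeries.from_values([10.0, 12.0, 11.0, 13.0, 12.0])
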