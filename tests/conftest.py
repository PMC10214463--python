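import numpy as np
import pytest

from sealtrip import synthetic


@pytest.fixture(scope="session")
def short_healthy_trip():
    """Three clean days of healthy diving (no drift, modest noise)."""
    cfg = synthetic.healthy_config(seed=11, trip_days=3.0,
                                   sensor_offset_end=0.0, noise_sd=0.1)
    return synthetic.simulate_trip(cfg)


@pytest.fixture(scope="session")
def sick_trip():
    """25-day sick-regime trip covering the day 8-20 illness window."""
    return synthetic.simulate_trip(synthetic.sick_config(seed=2, trip_days=25.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
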