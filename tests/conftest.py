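import numpy as np
import pytest

from nvcwave.series import UniformSeries
from nvcwave.synthetic import SyntheticConfig, generate_recording

MARGIN_RATE = 256.0 / 1224.0


@pytest.fixture(scope="session")
def short_recording():
    """One-hour continuous synthetic subject, shared across read-only tests."""
    cfg = SyntheticConfig(
        duration_s=3600.0, coupling_periods_s=(600.0,), coupling_strength=1.0, seed=42
    )
    return generate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(values, rate=MARGIN_RATE, units=""):
    return UniformSeries(np.asarray(values, dtype=float), rate=rate, units=units)
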