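import numpy as np
import pytest

import locodyn as ld


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def sine_series():
    """3-day, 60 s-sampled record factory with a single oscillation."""

    def make(period_h: float, depth: float = 0.9, offset: float = 1.0) -> ld.ActivitySeries:
        t = 60.0 * np.arange(4320)
        x = offset + depth * np.cos(2.0 * np.pi * t / (period_h * 3600.0))
        return ld.ActivitySeries(dt=60.0, values=np.maximum(x, 0.0))

    return make


@pytest.fixture
def telegraph_series():
    """Clean telegraph record (no noise, no modulation) plus its ground truth."""
    spec = ld.make_spec(
        "wt",
        seed=7,
        days=1.0,
        noise_sd=0.0,
        circadian_depth=0.0,
        ultradian=(),
        burst_sigma=0.0,
    )
    return ld.generate_series(spec)
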