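import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from arcseg import RegimeSpec, SubseqParams, TimeSeries, make_regime_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_series(rng):
    return rng.standard_normal(400)


@pytest.fixture
def two_regime():
    """Seeded 2-regime series with a known boundary at 300."""
    specs = [
        RegimeSpec("sine", period=25, duration=300, noise_db=20, seed=1),
        RegimeSpec("sawtooth", period=33, duration=300, noise_db=20, seed=2),
    ]
    series, truth = make_regime_series(specs)
    return series, truth, SubseqParams(L=25)
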