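from datetime import datetime

import numpy as np
import pytest

from clockcomp import ActivitySeries, LightRegime, LightSegment


@pytest.fixture
def rng():
    return np.random.default_rng(20140601)


def make_series(counts, bin_width=60, mode="DD", T=24.0, fly_id="fly",
                light_fraction=0.5):
    """Build a one-segment ActivitySeries around a raw count vector."""
    counts = np.asarray(counts, dtype=np.int64)
    seg = LightSegment(mode, len(counts), T, light_fraction)
    return ActivitySeries(
        fly_id=fly_id,
        bin_width=bin_width,
        start=datetime(2014, 6, 1),
        counts=counts,
        regime=LightRegime((seg,)),
    )


@pytest.fixture
def square_wave_series():
    """Noiseless 6-h on / 18-h off square wave, 8 days at 1-h bins."""
    day = [5] * 6 + [0] * 18
    return make_series(day * 8, bin_width=60)
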