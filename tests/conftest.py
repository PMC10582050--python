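import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231017)


def make_track(points, start="2016-01-01 00:00", hours=3, unit_id="lion_01"):
    """Build a GPS observation frame from (lon, lat) points at a fixed cadence."""
    t0 = pd.Timestamp(start, tz="UTC")
    return pd.DataFrame({
        "site_id": "site_000",
        "unit_id": unit_id,
        "timestamp": [t0 + i * pd.Timedelta(hours=hours) for i in range(len(points))],
        "lon": [p[0] for p in points],
        "lat": [p[1] for p in points],
        "method": "gps",
    })


@pytest.fixture
def scattered_track():
    """5 fixes pairwise far more than 200 m apart."""
    return make_track([(17.0 + 0.01 * i, -20.0) for i in range(5)])


@pytest.fixture
def bout_track():
    """4 fixes within 50 m of each other over 6 h."""
    m = 0.0002  # ~ 21 m of longitude at lat -20
    return make_track([(17.0, -20.0), (17.0 + m, -20.0),
                       (17.0, -20.0 + m), (17.0 + m, -20.0 + m)], hours=2)
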