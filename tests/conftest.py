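import numpy as np
import pandas as pd
import pytest

from geovalid.trajectory_io import Trajectory


def make_trajectory(points, t0="2010-11-04 12:00:00", tz="UTC", subject_id="T", speed=None, heading=None):
    """Trajectory from (dt_seconds, lat, lon) triples (dt relative to t0)."""
    base = pd.Timestamp(t0, tz="UTC")
    df = pd.DataFrame(
        {
            "t": [base + pd.Timedelta(seconds=s) for s, _, _ in points],
            "lat": [la for _, la, _ in points],
            "lon": [lo for _, _, lo in points],
        }
    )
    if speed is not None:
        df["speed"] = speed
    if heading is not None:
        df["heading"] = heading
    return Trajectory(subject_id=subject_id, fixes=df, tz=tz)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dwell_trajectory():
    """900 s of 1 Hz fixes jittered a few meters around one point."""
    r = np.random.default_rng(0)
    pts = []
    for s in range(900):
        pts.append((s, 32.2 + r.normal(0, 3) / 111_320, -110.9 + r.normal(0, 3) / 94_200))
    return make_trajectory(pts)
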