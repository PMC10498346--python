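import numpy as np
import pandas as pd
import pytest

from platformcrowd.geometry import make_platform
from platformcrowd.trajectory_io import TrajectorySet


@pytest.fixture(scope="session")
def platform():
    return make_platform("none")


@pytest.fixture(scope="session")
def platform_narrow():
    return make_platform("narrow")


@pytest.fixture(scope="session")
def platform_wide():
    return make_platform("wide")


def make_static_ts(points, n_frames=10, frame_rate=50.0, start_frame=0):
    """TrajectorySet of motionless agents repeated over n_frames."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    frames = np.arange(start_frame, start_frame + n_frames)
    recs = pd.DataFrame(
        {
            "person_id": np.repeat(np.arange(1, n + 1), n_frames),
            "frame": np.tile(frames, n),
            "x": np.repeat(points[:, 0], n_frames),
            "y": np.repeat(points[:, 1], n_frames),
        }
    )
    return TrajectorySet(records=recs, frame_rate=frame_rate)


@pytest.fixture(scope="session")
def five_agent_points():
    """Asymmetric five-person arrangement used by the oracle checks."""
    return np.array(
        [[-3.0, 1.2], [2.5, -1.0], [0.0, 0.3], [6.0, 2.0], [-7.0, -2.0]]
    )
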