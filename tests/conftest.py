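import numpy as np
import pytest

from dyadcoord.kinematics import SpeedSeries
from dyadcoord.pose_io import CANONICAL_MARKERS, MarkerId, PoseTrack
from dyadcoord.synth import EpisodeSpec, simulate_dyad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_speed(values, fps=60.0, marker=MarkerId("A", "left")):
    return SpeedSeries(fps=fps, values=np.asarray(values, dtype=float), marker=marker)


@pytest.fixture
def speed_factory():
    return make_speed


@pytest.fixture
def noise_speeds(rng):
    """Independent white-noise speed series for all four hand markers."""
    return {
        m: make_speed(np.abs(rng.normal(size=1800)), marker=m)
        for m in CANONICAL_MARKERS
    }


@pytest.fixture(scope="session")
def short_session():
    """One 90-s synthetic session exercising all three episode modes."""
    episodes = [
        EpisodeSpec(0.0, 30.0, "coupled", leader="A", lag=150.0, coupling=0.9),
        EpisodeSpec(30.0, 60.0, "independent"),
        EpisodeSpec(60.0, 90.0, "stillness"),
    ]
    return simulate_dyad(episodes, duration=90.0, seed=7)


@pytest.fixture
def tiny_track():
    """A 2-frame track with hand A-left at (10,20,0.99) then (13,24,0.98)."""
    n = 2
    data = {}
    for i, m in enumerate(CANONICAL_MARKERS):
        data[m] = np.array(
            [[10.0 + i, 20.0 + i, 0.99], [13.0 + i, 24.0 + i, 0.98]]
        )
    return PoseTrack(fps=60.0, data=data)
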