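import numpy as np
import pytest

from waterreach import PoseTracks, SpoutGeometry, SynthConfig, generate_session
from waterreach.synth import default_geometry

RATE = 60.0


@pytest.fixture(scope="session")
def geometry() -> SpoutGeometry:
    """Simple platform/spout layout: platform at y=200, spout 40 px above."""
    return SpoutGeometry(
        spout_distance_px=40.0,
        platform_y=200.0,
        spout_y=160.0,
        platform_x=90.0,
        spout_x=112.0,
    )


def make_tracks(
    left_paw_xy: np.ndarray,
    geometry: SpoutGeometry,
    rate: float = RATE,
    mouth_xy: tuple[float, float] | None = None,
    confidence: np.ndarray | None = None,
) -> PoseTracks:
    """Hand-built tracks with a scripted left paw and static landmarks."""
    n = len(left_paw_xy)
    conf = np.ones(n) if confidence is None else np.asarray(confidence, float)
    mouth = mouth_xy or (107.0, 168.0)

    def static(x, y):
        return np.column_stack([np.full(n, x), np.full(n, y), np.ones(n)])

    arrays = {
        "left_paw": np.column_stack(
            [left_paw_xy[:, 0], left_paw_xy[:, 1], conf]
        ),
        "right_paw": static(124.0, geometry.platform_y),
        "mouth": static(*mouth),
        "platform": static(geometry.platform_x, geometry.platform_y),
        "spout": static(geometry.spout_x, geometry.spout_y),
    }
    return PoseTracks.from_arrays(arrays, rate)


@pytest.fixture()
def resting_tracks(geometry) -> PoseTracks:
    """Paw resting on the platform for a full 16-s trial."""
    n = int(16 * RATE)
    xy = np.column_stack([np.full(n, 100.0), np.full(n, geometry.platform_y)])
    return make_tracks(xy, geometry)


@pytest.fixture(scope="session")
def small_session():
    """Noise-free 20-trial session without imaging (shared, read-only)."""
    cfg = SynthConfig(n_trials=20, seed=42, pose_dropout_probability=0.0)
    return generate_session(cfg, include_imaging=False)


@pytest.fixture(scope="session")
def synth_geometry():
    return default_geometry(SynthConfig())
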