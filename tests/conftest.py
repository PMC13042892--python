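import numpy as np
import pytest

from vigilkit.types import ArenaGeometry, Hypnogram, PoseTrack


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture
def all_nrem_30min() -> Hypnogram:
    return Hypnogram(np.array(["NREM"] * 180), 10.0, 0.0)


def make_track(
    segments: list[tuple[float, np.ndarray]],
    fps: float = 40.0,
    head_sign: float = 1.0,
    total_s: float | None = None,
) -> PoseTrack:
    """Build a pose track from (arrival_time_s, position) waypoints.

    The centroid moves linearly between consecutive waypoints (constant
    speed per leg) and holds the last position.  head/tail_base lie 1.5 cm
    along the motion direction times ``head_sign`` (-1 = walking backward).
    """
    times = np.array([t for t, _ in segments])
    pts = np.array([p for _, p in segments], dtype=float)
    end = total_s if total_s is not None else times[-1] + 1.0
    t = np.arange(0.0, end, 1.0 / fps)
    xy = np.column_stack(
        [np.interp(t, times, pts[:, 0]), np.interp(t, times, pts[:, 1])]
    )
    vel = np.gradient(xy, 1.0 / fps, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    u = np.zeros_like(xy)
    last = np.array([1.0, 0.0])
    for i in range(len(t)):
        if speed[i] > 1.0:
            last = vel[i] / speed[i]
        u[i] = last
    u *= head_sign
    return PoseTrack(
        fps,
        {"body_centroid": xy, "head": xy + 1.5 * u, "tail_base": xy - 1.5 * u},
    )
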