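import numpy as np
import pytest

from medreba.landmark_io import (BODY_POINT_COUNT, CameraStream,
                                 LandmarkFrame, LandmarkPoint)


def make_body_frame(frame_index=0, camera_label="A", jitter=0.0, rng=None):
    """A schema-valid body frame with deterministic (optionally jittered)
    coordinates."""
    rng = rng or np.random.default_rng(frame_index)
    pts = []
    for i in range(BODY_POINT_COUNT):
        x = 0.3 + 0.01 * i + (rng.normal(0, jitter) if jitter else 0.0)
        y = 0.2 + 0.015 * i
        pts.append(LandmarkPoint(x, y, 0.0, 1.0))
    return LandmarkFrame(kind="body", points=tuple(pts),
                         frame_index=frame_index, timestamp=frame_index / 30.0,
                         camera_label=camera_label)


def make_body_stream(n_frames=3, camera_label="A", fps=30.0):
    frames = [make_body_frame(i, camera_label) for i in range(n_frames)]
    return CameraStream(camera_label=camera_label, kind="body", frames=frames,
                        fps=fps)


@pytest.fixture
def body_stream():
    return make_body_stream()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
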