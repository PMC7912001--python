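import numpy as np
import pandas as pd
import pytest

from freerange.simulate import (
    BlobSpec,
    TrajectorySpec,
    generate_trajectory,
    render_video,
)
from freerange.tracking import VideoMeta, track_video


@pytest.fixture
def make_static_track():
    """Render a motionless blob and track it; returns (track, video)."""

    def _make(major_m=0.5, minor_m=0.25, orientation_deg=0.0,
              duration_s=2.0, fps=5.0, resolution_px=720, dropout_rate=0.0,
              seed=0):
        path = generate_trajectory(
            TrajectorySpec(duration_s=duration_s, fps=fps,
                           profile="stationary", seed=seed)
        )
        blob = BlobSpec(major_axis_m=major_m, minor_axis_m=minor_m,
                        orientation_deg=orientation_deg,
                        dropout_rate=dropout_rate)
        video = render_video(path, blob, resolution_px=resolution_px, seed=seed)
        meta = VideoMeta(fps=fps, resolution_px=resolution_px)
        return track_video(video, meta), video

    return _make


@pytest.fixture
def make_synthetic_track():
    """Fabricate a Track directly from per-frame ground truth columns."""

    def _make(x_m, y_m, fps=25.0, detected=None, minor_major=None):
        n = len(x_m)
        detected = np.ones(n, dtype=bool) if detected is None else np.asarray(detected)
        if minor_major is None:
            major = np.full(n, 0.4)
            minor = np.full(n, 0.2)
        else:
            minor, major = minor_major
        rec = pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_s": np.arange(n) / fps,
                "detected": detected,
                "centroid_x_m": np.where(detected, x_m, np.nan),
                "centroid_y_m": np.where(detected, y_m, np.nan),
                "ellipse_x_m": np.where(detected, x_m, np.nan),
                "ellipse_y_m": np.where(detected, y_m, np.nan),
                "major_axis_m": np.where(detected, major, np.nan),
                "minor_axis_m": np.where(detected, minor, np.nan),
                "orientation_deg": 0.0,
            }
        )
        from freerange.tracking import Track

        return Track(VideoMeta(fps=fps, resolution_px=720), rec)

    return _make
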