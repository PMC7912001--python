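"""The seven per-hen open-field movement parameters.

A track is split into tumbling 10-s windows; each window's path length
is the sum of displacements between successive detected centroids
inside the window.  A window is *stationary* when its path length is
below the 5-cm threshold (cumulative path, the stricter reading of
"5-cm movement within a 10-s period"), and sub-threshold windows
contribute zero to the distance moved so detection jitter cannot
inflate it.  The seven summaries:

percent detection, distance moved (m), mean shape, SD shape,
max 10-s move (m), stationary time (s), move ratio.

Shape is minor/major axis per detected frame: 1 is circular, 0.5 an
ellipse twice as long as wide.  The move ratio is moving time over
non-moving time; a track with no stationary windows has an undefined
(infinite) ratio, reported as ``inf`` and excluded from downstream
ratio statistics.  Hens whose detection falls below 75% are excluded
from analysis by :func:`filter_by_detection`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Track, percent_detection

#: cumulative within-window path (m) below which a window is stationary
STATIONARY_THRESHOLD_M = 0.05
WINDOW_S = 10.0
#: windows with fewer detected frames than this fraction are indeterminate
MIN_DETECTED_FRACTION = 0.5
DETECTION_CUTOFF_PCT = 75.0


@dataclass(frozen=True)
class OFTMovementMetrics:
    """Per-hen movement summary (the seven tracked parameters)."""

    percent_detection: float
    distance_moved_m: float
    mean_shape: float
    sd_shape: float
    max_10s_move_m: float
    stationary_time_s: float
    move_ratio: float            # inf when no stationary time
    moving_fraction: float       # moving / (moving + non-moving) time

    def as_dict(self) -> dict:
        return {
            "percent_detection": self.percent_detection,
            "distance_moved_m": self.distance_moved_m,
            "mean_shape": self.mean_shape,
            "sd_shape": self.sd_shape,
            "max_10s_move_m": self.max_10s_move_m,
            "stationary_time_s": self.stationary_time_s,
            "move_ratio": self.move_ratio,
            "moving_fraction": self.moving_fraction,
        }


def window_split(track: Track, width_s: float = WINDOW_S,
                 use_centroid: bool = True,
                 threshold_m: float = STATIONARY_THRESHOLD_M,
                 keep_partial: bool = True) -> pd.DataFrame:
    """Split a track into tumbling windows with per-window path lengths.

    Returns one row per window: ``window, start_s, end_s, width_s,
    path_length_m, detected_fraction, is_stationary`` where
    ``is_stationary`` is NA for windows with under 50% detection
    (stationarity cannot be judged from too few fixes).  A trailing
    partial window is kept with its stationarity threshold pro-rated to
    its width, unless ``keep_partial`` is false.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    rec = track.records
    fps = track.meta.fps
    duration = len(rec) / fps
    xcol = "centroid_x_m" if use_centroid else "ellipse_x_m"
    ycol = "centroid_y_m" if use_centroid else "ellipse_y_m"

    n_windows = int(math.ceil(duration / width_s - 1e-9))
    rows = []
    for w in range(n_windows):
        start, end = w * width_s, min((w + 1) * width_s, duration)
        if end - start < width_s and not keep_partial:
            break
        i0, i1 = int(round(start * fps)), int(round(end * fps))
        chunk = rec.iloc[i0:i1]
        det = chunk[chunk["detected"]]
        frac = len(det) / max(len(chunk), 1)
        if len(det) >= 2:
            path = float(
                np.hypot(np.diff(det[xcol]), np.diff(det[ycol])).sum()
            )
        else:
            path = 0.0
        width = end - start
        if frac < MIN_DETECTED_FRACTION:
            stationary = pd.NA
        else:
            stationary = bool(path < threshold_m * (width / WINDOW_S))
        rows.append(
            {
                "window": w,
                "start_s": start,
                "end_s": end,
                "width_s": width,
                "path_length_m": path,
                "detected_fraction": frac,
                "is_stationary": stationary,
            }
        )
    out = pd.DataFrame(rows)
    out["is_stationary"] = out["is_stationary"].astype("boolean")
    return out


def stationary_time(windows: pd.DataFrame) -> float:
    """Total seconds in stationary windows (sub-5-cm path per 10 s)."""
    mask = windows["is_stationary"].fillna(False).to_numpy(dtype=bool)
    return float(windows.loc[mask, "width_s"].sum())


def distance_moved(windows: pd.DataFrame, suppress_stationary: bool = True) -> float:
    """Total distance (m); stationary windows contribute zero by default."""
    if suppress_stationary:
        moving = ~windows["is_stationary"].fillna(False).to_numpy(dtype=bool)
        return float(windows.loc[moving, "path_length_m"].sum())
    return float(windows["path_length_m"].sum())


def max_10s_move(windows: pd.DataFrame) -> float:
    """Largest single-window path length (m)."""
    return float(windows["path_length_m"].max())


def shape_stats(track: Track) -> tuple[float, float]:
    """Mean and SD of minor/major axis ratio over detected frames.

    Raises on a track with zero detected frames (shape undefined).
    """
    det = track.records[track.records["detected"]]
    if len(det) == 0:
        raise ValueError("no detected frames: shape undefined")
    shape = (det["minor_axis_m"] / det["major_axis_m"]).to_numpy()
    return float(shape.mean()), float(shape.std(ddof=0))


def move_ratio(windows: pd.DataFrame) -> float:
    """Moving time / non-moving time over determinate windows.

    Fully stationary -> 0; no stationary windows -> ``inf`` (a defined
    sentinel distinct from every numeric value); no determinate windows
    -> NaN.
    """
    judged = windows.dropna(subset=["is_stationary"])
    if len(judged) == 0:
        return float("nan")
    stat = judged["is_stationary"].to_numpy(dtype=bool)
    t_stat = float(judged.loc[stat, "width_s"].sum())
    t_move = float(judged.loc[~stat, "width_s"].sum())
    if t_stat == 0.0:
        return float("inf") if t_move > 0 else float("nan")
    return t_move / t_stat


def moving_fraction(windows: pd.DataFrame) -> float:
    """Moving / (moving + non-moving) time — the logit-safe variant."""
    judged = windows.dropna(subset=["is_stationary"])
    total = float(judged["width_s"].sum())
    if total == 0.0:
        return float("nan")
    stat = judged["is_stationary"].to_numpy(dtype=bool)
    return float(judged.loc[~stat, "width_s"].sum()) / total


def movement_metrics(track: Track, width_s: float = WINDOW_S,
                     threshold_m: float = STATIONARY_THRESHOLD_M,
                     use_centroid: bool = True) -> OFTMovementMetrics:
    """Compute all seven per-hen movement parameters for one track."""
    windows = window_split(track, width_s=width_s, threshold_m=threshold_m,
                           use_centroid=use_centroid)
    mean_shape, sd_shape = shape_stats(track)
    return OFTMovementMetrics(
        percent_detection=percent_detection(track),
        distance_moved_m=distance_moved(windows),
        mean_shape=mean_shape,
        sd_shape=sd_shape,
        max_10s_move_m=max_10s_move(windows),
        stationary_time_s=stationary_time(windows),
        move_ratio=move_ratio(windows),
        moving_fraction=moving_fraction(windows),
    )


def filter_by_detection(metrics: pd.DataFrame,
                        threshold: float = DETECTION_CUTOFF_PCT
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude hens whose tracker detection is below 75%.

    ``metrics`` needs a ``percent_detection`` column.  Returns
    ``(included, report)`` where the report lists every excluded hen
    and the reason.  The boundary is strict: exactly 75% is included.
    """
    low = metrics["percent_detection"] < threshold
    report = metrics.loc[low].copy()
    report["reason"] = [
        f"automated recognition detected {p:.1f}% (< {threshold:g}%) of movements"
        for p in report["percent_detection"]
    ]
    return metrics.loc[~low].copy(), report
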