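"""Single-hen blob tracking in open-field arena video.

Each frame is reduced to 1/4 of its original size (area interpolation),
thresholded for the dark hen against the pale wooden floor, and the
largest connected dark region within the area gates is kept.  An
ellipse is fitted to the blob from its second-order image moments; the
per-frame record stream keeps both the blob centre of mass and the
fitted-ellipse centre, plus major/minor axis lengths and orientation.
A 5-min file at 25 fps with full detection yields 25 x 60 x 5 = 7500
records.

Calibration: pixels convert to metres through the known arena side
(1.8 m) spanning the frame, computed on the downscaled grid so the
reduction factor cancels from every metric output.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.measure import label
from skimage.transform import downscale_local_mean, resize


@dataclass(frozen=True)
class VideoMeta:
    """Acquisition metadata and calibration for one open-field video."""

    fps: float = 25.0
    resolution_px: int = 1440       # source frame side (square)
    downscale_factor: float = 0.25
    arena_side_m: float = 1.8

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not (0 < self.downscale_factor <= 1):
            raise ValueError("downscale_factor must be in (0, 1]")
        if self.arena_side_m <= 0:
            raise ValueError("arena_side_m must be > 0")

    @property
    def downscaled_px(self) -> int:
        return int(round(self.resolution_px * self.downscale_factor))

    @property
    def px_per_m(self) -> float:
        """Calibration on the downscaled grid (arena side spans the frame)."""
        return self.downscaled_px / self.arena_side_m


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding and area gating for the dark-blob detector."""

    threshold: float = 128.0        # grey level; blob pixels are darker
    min_area_px: float = 5.0        # on the downscaled grid
    max_area_px: float = float("inf")
    adaptive: bool = False          # local-mean threshold instead of fixed
    adaptive_block: int = 51
    adaptive_offset: float = 10.0


@dataclass(frozen=True)
class EllipseFit:
    centre_xy: tuple        # fitted-ellipse centre (col, row), px
    centroid_xy: tuple      # blob centre of mass (col, row), px
    major_px: float
    minor_px: float
    orientation_deg: float  # CCW from image x axis (y up), in [0, 180)


@dataclass
class Track:
    """Per-frame record stream: one row per frame, detected or not."""

    meta: VideoMeta
    records: pd.DataFrame = field(repr=False)

    COLUMNS = (
        "frame", "time_s", "detected",
        "centroid_x_m", "centroid_y_m", "ellipse_x_m", "ellipse_y_m",
        "major_axis_m", "minor_axis_m", "orientation_deg",
    )

    def __post_init__(self):
        frames = self.records["frame"].to_numpy()
        if len(frames) and not np.all(np.diff(frames) > 0):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fps={self.meta.fps}\n")
            fh.write(f"# resolution_px={self.meta.resolution_px}\n")
            fh.write(f"# downscale_factor={self.meta.downscale_factor}\n")
            fh.write(f"# arena_side_m={self.meta.arena_side_m}\n")
            self.records.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "Track":
        meta_kv = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, val = line[1:].strip().split("=", 1)
                meta_kv[key.strip()] = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            records = pd.read_csv(fh)
        meta = VideoMeta(
            fps=meta_kv.get("fps", 25.0),
            resolution_px=int(meta_kv.get("resolution_px", 1440)),
            downscale_factor=meta_kv.get("downscale_factor", 0.25),
            arena_side_m=meta_kv.get("arena_side_m", 1.8),
        )
        return cls(meta, records)


def detect_blob(frame: np.ndarray, params: DetectionParams | None = None) -> np.ndarray | None:
    """Return the mask of the largest dark region within the area gates.

    ``frame`` must be single-channel.  Absence of any admissible blob is
    a valid outcome and returns None.
    """
    if frame.ndim != 2:
        raise ValueError("frame must be single-channel (2-D)")
    params = params or DetectionParams()
    img = frame.astype(np.float64, copy=False)
    if params.adaptive:
        from skimage.filters import threshold_local

        local = threshold_local(img, params.adaptive_block,
                                offset=params.adaptive_offset)
        binary = img < local
    else:
        binary = img < params.threshold
    if not binary.any():
        return None
    labels = label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    admissible = np.flatnonzero(
        (counts >= params.min_area_px) & (counts <= params.max_area_px)
    )
    if admissible.size == 0:
        return None
    best = admissible[np.argmax(counts[admissible])]
    return labels == best


def fit_ellipse(mask: np.ndarray) -> EllipseFit | None:
    """Moments-based ellipse fit; None for degenerate masks (< 5 px)."""
    rows, cols = np.nonzero(mask)
    n = rows.size
    if n < 5:
        return None
    cy, cx = rows.mean(), cols.mean()
    # math coordinates: x = col, y = -row (y grows upward)
    x = cols - cx
    y = -(rows - cy)
    # +1/12 pixel-integration variance keeps thin blobs non-degenerate
    mxx = (x * x).mean() + 1.0 / 12.0
    myy = (y * y).mean() + 1.0 / 12.0
    mxy = (x * y).mean()
    common = np.sqrt((mxx - myy) ** 2 + 4 * mxy ** 2)
    lam1 = (mxx + myy + common) / 2.0
    lam2 = (mxx + myy - common) / 2.0
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    theta = 0.5 * np.arctan2(2 * mxy, mxx - myy)
    return EllipseFit(
        centre_xy=(cx, cy),
        centroid_xy=(cx, cy),
        major_px=major,
        minor_px=minor,
        orientation_deg=float(np.degrees(theta) % 180.0),
    )


def _downscale(frame: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return frame.astype(np.float64, copy=False)
    inv = 1.0 / factor
    if abs(inv - round(inv)) < 1e-9 and frame.shape[0] % round(inv) == 0:
        k = int(round(inv))
        return downscale_local_mean(frame.astype(np.float64), (k, k))
    out = tuple(int(round(s * factor)) for s in frame.shape)
    return resize(frame.astype(np.float64), out, anti_aliasing=True,
                  preserve_range=True)


def track_video(frames, meta: VideoMeta, params: DetectionParams | None = None) -> Track:
    """Run detection + ellipse fitting over a frame sequence.

    ``frames`` is any iterable of equal-sized single-channel arrays.
    Every frame yields exactly one record; undetected frames keep their
    slot with empty geometry so downstream windows can measure
    per-window detection.
    """
    params = params or DetectionParams()
    ppm = meta.px_per_m
    rows = []
    shape = None
    for i, frame in enumerate(frames):
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValueError(f"frame {i} resolution {frame.shape} != {shape}")
        small = _downscale(frame, meta.downscale_factor)
        mask = detect_blob(small, params)
        fit = fit_ellipse(mask) if mask is not None else None
        if fit is None:
            rows.append(
                {
                    "frame": i, "time_s": i / meta.fps, "detected": False,
                    "centroid_x_m": np.nan, "centroid_y_m": np.nan,
                    "ellipse_x_m": np.nan, "ellipse_y_m": np.nan,
                    "major_axis_m": np.nan, "minor_axis_m": np.nan,
                    "orientation_deg": np.nan,
                }
            )
        else:
            rows.append(
                {
                    "frame": i,
                    "time_s": i / meta.fps,
                    "detected": True,
                    "centroid_x_m": fit.centroid_xy[0] / ppm,
                    "centroid_y_m": fit.centroid_xy[1] / ppm,
                    "ellipse_x_m": fit.centre_xy[0] / ppm,
                    "ellipse_y_m": fit.centre_xy[1] / ppm,
                    "major_axis_m": fit.major_px / ppm,
                    "minor_axis_m": fit.minor_px / ppm,
                    "orientation_deg": fit.orientation_deg,
                }
            )
    if not rows:
        raise ValueError("empty frame sequence")
    return Track(meta, pd.DataFrame(rows, columns=list(Track.COLUMNS)))


def percent_detection(track: Track) -> float:
    """100 x detected frames / total frames."""
    if len(track) == 0:
        raise ValueError("empty track")
    return 100.0 * float(track.records["detected"].sum()) / len(track)


def read_png_dir(directory: str):
    """Yield frames from a directory of PNGs in filename order."""
    paths = sorted(glob.glob(os.path.join(directory, "*.png")))
    if not paths:
        raise ValueError(f"no PNG frames found in {directory}")
    for p in paths:
        frame = iio.imread(p)
        if frame.ndim == 3:
            frame = frame.mean(axis=2)
        yield np.asarray(frame)
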