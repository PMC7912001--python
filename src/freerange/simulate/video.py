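"""Render a ground-truth trajectory as overhead arena video.

The hen is a filled dark ellipse on a paler uniform background (a dark
bird on pale wooden flooring).  Dropout frames — the renderer's stand-in
for the real tracker's failure on pale hens — contain background only.
Frames are rendered lazily so long videos never need to be held in
memory at once.

Pixel convention: the arena x axis maps to image columns and y to rows
(row = y * px_per_m); orientation is degrees counterclockwise from the
image x axis with y pointing up, folded to [0, 180).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BlobSpec:
    """Geometry and photometry of the rendered hen blob."""

    major_axis_m: float = 0.30
    minor_axis_m: float = 0.18
    orientation_deg: float = 0.0
    intensity: int = 60       # blob grey level (darker than background)
    dropout_rate: float = 0.0
    noise_sigma: float = 0.0  # additive Gaussian pixel noise, grey levels

    def __post_init__(self):
        if not (0 < self.minor_axis_m <= self.major_axis_m):
            raise ValueError("require 0 < minor_axis_m <= major_axis_m")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


class SyntheticVideo:
    """Lazily rendered frame sequence plus its per-frame ground truth.

    ``truth`` has one row per frame: ``frame, x_m, y_m, major_m,
    minor_m, orient_deg, visible``.
    """

    def __init__(self, path: pd.DataFrame, blob: BlobSpec, arena_side_m: float,
                 resolution_px: int, background: int, seed: int):
        if blob.major_axis_m >= arena_side_m:
            raise ValueError("blob major axis must be smaller than the arena side")
        self.blob = blob
        self.arena_side_m = float(arena_side_m)
        self.resolution_px = int(resolution_px)
        self.background = int(background)
        self.seed = int(seed)
        self.px_per_m = self.resolution_px / self.arena_side_m

        rng = np.random.default_rng(seed)
        n = len(path)
        visible = rng.random(n) >= blob.dropout_rate
        self.truth = pd.DataFrame(
            {
                "frame": path["frame"].to_numpy(),
                "x_m": path["x_m"].to_numpy(),
                "y_m": path["y_m"].to_numpy(),
                "major_m": blob.major_axis_m,
                "minor_m": blob.minor_axis_m,
                "orient_deg": blob.orientation_deg % 180.0,
                "visible": visible,
            }
        )

    def __len__(self) -> int:
        return len(self.truth)

    def render_frame(self, i: int) -> np.ndarray:
        """Render frame i as a 2-D uint8 array."""
        row = self.truth.iloc[i]
        frame = np.full(
            (self.resolution_px, self.resolution_px), self.background, dtype=np.float64
        )
        if row["visible"]:
            ppm = self.px_per_m
            cx, cy = row["x_m"] * ppm, row["y_m"] * ppm  # (col, row)
            a = 0.5 * self.blob.major_axis_m * ppm
            b = 0.5 * self.blob.minor_axis_m * ppm
            theta = np.deg2rad(self.blob.orientation_deg)
            r0 = max(int(np.floor(cy - a)) - 1, 0)
            r1 = min(int(np.ceil(cy + a)) + 2, self.resolution_px)
            c0 = max(int(np.floor(cx - a)) - 1, 0)
            c1 = min(int(np.ceil(cx + a)) + 2, self.resolution_px)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            x = cc - cx
            y = -(rr - cy)  # image rows grow downward; math y grows up
            u = x * np.cos(theta) + y * np.sin(theta)
            v = -x * np.sin(theta) + y * np.cos(theta)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            patch = frame[r0:r1, c0:c1]
            patch[inside] = self.blob.intensity
        if self.blob.noise_sigma > 0:
            # per-frame child seed: deterministic regardless of access order
            frng = np.random.default_rng([self.seed, i])
            frame += frng.normal(0.0, self.blob.noise_sigma, frame.shape)
        return np.clip(frame, 0, 255).astype(np.uint8)

    def iter_frames(self):
        for i in range(len(self)):
            yield self.render_frame(i)

    def __iter__(self):
        return self.iter_frames()

    def to_frames(self) -> list[np.ndarray]:
        """Materialise all frames (small videos only)."""
        return list(self.iter_frames())

    def write_png_dir(self, directory: str) -> None:
        """Write frames as zero-padded PNGs plus the truth CSV."""
        os.makedirs(directory, exist_ok=True)
        width = len(str(len(self) - 1))
        for i, frame in enumerate(self.iter_frames()):
            iio.imwrite(os.path.join(directory, f"frame_{i:0{width}d}.png"), frame)
        self.truth.to_csv(os.path.join(directory, "truth.csv"), index=False)


def render_video(path: pd.DataFrame, blob: BlobSpec, arena_side_m: float = 1.8,
                 resolution_px: int = 360, background: int = 200,
                 seed: int = 0) -> SyntheticVideo:
    """Render a trajectory (from :func:`generate_trajectory`) to video.

    Parameters
    ----------
    path : DataFrame with x_m, y_m per frame.
    resolution_px : side of the square source frame in pixels.
    background : background grey level, must exceed the blob intensity.
    """
    if background <= blob.intensity:
        raise ValueError("background must be brighter than the blob")
    return SyntheticVideo(path, blob, arena_side_m, resolution_px, background, seed)
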