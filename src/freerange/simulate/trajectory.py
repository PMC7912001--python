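"""Ground-truth arena trajectories for a single hen.

Positions are in metres inside a square arena (1.8 m side by default,
the open-field box size).  Profiles:

``stationary``
    The hen never moves (freezing, the classic open-field fear response).
``wander``
    A correlated random walk at slow forage-like speed.
``flighty``
    Alternating freezes and fast dashes (panic locomotion).
``scheduled``
    Piecewise-constant speed segments with analytically known path
    length; motion is a billiard path (straight lines, wall reflections)
    so the realised path length equals ``speed x duration`` per segment
    whenever no reflection falls inside a frame step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROFILES = ("stationary", "wander", "flighty", "scheduled")


@dataclass(frozen=True)
class TrajectorySpec:
    """Specification of one synthetic arena trajectory."""

    duration_s: float
    fps: float = 25.0
    arena_side_m: float = 1.8
    profile: str = "wander"
    #: for profile="scheduled": list of (start_s, end_s, speed_m_per_s)
    schedule: tuple = field(default=())
    seed: int = 0
    start_xy: tuple | None = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.arena_side_m <= 0:
            raise ValueError("arena_side_m must be > 0")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; choose from {PROFILES}")
        if self.profile == "scheduled":
            segs = sorted(self.schedule, key=lambda s: s[0])
            last_end = 0.0
            for start, end, speed in segs:
                if not (0.0 <= start < end <= self.duration_s):
                    raise ValueError(
                        f"schedule segment ({start}, {end}) outside [0, {self.duration_s}]"
                    )
                if start < last_end:
                    raise ValueError("schedule segments overlap")
                if speed < 0:
                    raise ValueError("segment speed must be >= 0")
                last_end = end

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def _reflect(u: float, lo: float, hi: float) -> tuple[float, int]:
    """Fold u into [lo, hi] by mirror reflection; return (value, sign flips)."""
    span = hi - lo
    flips = 0
    while u < lo or u > hi:
        if u < lo:
            u = 2 * lo - u
        else:
            u = 2 * hi - u
        flips += 1
    return u, flips


def generate_trajectory(spec: TrajectorySpec) -> pd.DataFrame:
    """Generate one per-frame ground-truth path.

    Returns a DataFrame with columns ``frame, time_s, x_m, y_m`` and the
    realised path length stored in ``df.attrs["path_length_m"]``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    side = spec.arena_side_m
    # keep the whole blob clear of the walls (and of the frame edges)
    margin = 0.15 * side
    lo, hi = margin, side - margin
    if spec.start_xy is not None:
        x0, y0 = spec.start_xy
    elif spec.profile == "scheduled":
        x0, y0 = lo, side / 2.0  # run along +x from the margin
    else:
        x0 = y0 = side / 2.0

    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = x0, y0

    if spec.profile == "stationary":
        xs[:], ys[:] = x0, y0
    elif spec.profile in ("wander", "flighty"):
        if spec.profile == "wander":
            speeds = np.full(n, 0.06) * np.exp(0.3 * rng.standard_normal(n))
        else:
            # flighty: ~70% freeze, 30% dash at high speed, in runs
            state = 0.0
            speeds = np.empty(n)
            for i in range(n):
                if rng.random() < 1.0 / (2.0 * spec.fps):  # switch ~every 2 s
                    state = 1.0 - state
                speeds[i] = 0.5 * state
        heading = rng.uniform(0, 2 * np.pi)
        for i in range(1, n):
            heading += 0.25 * rng.standard_normal()
            step = speeds[i] / spec.fps
            x = xs[i - 1] + step * np.cos(heading)
            y = ys[i - 1] + step * np.sin(heading)
            x, fx = _reflect(x, lo, hi)
            y, fy = _reflect(y, lo, hi)
            if fx % 2:
                heading = np.pi - heading
            if fy % 2:
                heading = -heading
            xs[i], ys[i] = x, y
    else:  # scheduled
        segs = sorted(spec.schedule, key=lambda s: s[0])
        heading = 0.0  # along +x; deterministic so path length is analytic
        times = np.arange(n) / spec.fps
        speed_at = np.zeros(n)
        for start, end, speed in segs:
            speed_at[(times >= start) & (times < end)] = speed
        for i in range(1, n):
            step = speed_at[i - 1] / spec.fps
            x = xs[i - 1] + step * np.cos(heading)
            y = ys[i - 1] + step * np.sin(heading)
            x, fx = _reflect(x, lo, hi)
            y, fy = _reflect(y, lo, hi)
            if fx % 2:
                heading = np.pi - heading
            if fy % 2:
                heading = -heading
            xs[i], ys[i] = x, y

    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / spec.fps,
            "x_m": xs,
            "y_m": ys,
        }
    )
    df.attrs["path_length_m"] = float(
        np.hypot(np.diff(xs), np.diff(ys)).sum()
    )
    df.attrs["arena_side_m"] = side
    df.attrs["fps"] = spec.fps
    return df
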