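"""Synthetic directional RFID pop-hole logs.

Each hen has a per-day schedule of range-visit episodes; a genuine
episode emits one ``out`` and one ``in`` crossing.  False reads — the
incomplete transitions the real system records when a hen lingers in
the pop-hole — are injected as extra same-direction events shortly
after a genuine read, and are flagged in the ground truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: pop-holes open at 09:15; episodes must fall in the open window
POPHOLE_OPEN_S = 9 * 3600 + 15 * 60
POPHOLE_CLOSE_S = 19 * 3600


@dataclass(frozen=True)
class RangingSchedule:
    """Per-day visit episodes for one hen.

    ``episodes`` maps day index (0-based) to a list of
    (exit_time_s, entry_time_s) pairs, seconds since midnight.
    """

    hen_id: str
    episodes: dict = field(default_factory=dict)
    n_days: int = 45
    false_read_rate: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.false_read_rate <= 1.0):
            raise ValueError("false_read_rate must be in [0, 1]")
        for day, eps in self.episodes.items():
            if not (0 <= day < self.n_days):
                raise ValueError(f"day {day} outside 0..{self.n_days - 1}")
            prev_entry = -1.0
            for exit_s, entry_s in sorted(eps):
                if not (POPHOLE_OPEN_S <= exit_s < entry_s <= POPHOLE_CLOSE_S):
                    raise ValueError(
                        f"episode ({exit_s}, {entry_s}) outside pop-hole hours"
                    )
                if exit_s < prev_entry:
                    raise ValueError("episodes overlap")
                prev_entry = entry_s


def generate_rfid_log(
    schedules: list[RangingSchedule],
    seed: int = 0,
    start_date: dt.date = dt.date(2018, 10, 1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit an event log plus ground truth for a cohort of schedules.

    Returns ``(events, truth)``:

    * events — columns ``date, time, tag_id, direction, injected``
      (injected marks false reads; drop the column to get the raw log),
      sorted by tag then timestamp.
    * truth — per hen per day ``tag_id, day, date, outside_s``.
    """
    rng = np.random.default_rng(seed)
    ev_rows, truth_rows = [], []
    for sched in schedules:
        n_days = sched.n_days
        daily = np.zeros(n_days)
        for day in range(n_days):
            date = start_date + dt.timedelta(days=day)
            for exit_s, entry_s in sorted(sched.episodes.get(day, [])):
                daily[day] += entry_s - exit_s
                for t, direction in ((exit_s, "out"), (entry_s, "in")):
                    ev_rows.append(_event(date, t, sched.hen_id, direction, False))
                    if rng.random() < sched.false_read_rate:
                        # incomplete transition: duplicate read ~2 s later
                        ev_rows.append(
                            _event(date, t + 2.0, sched.hen_id, direction, True)
                        )
        for day in range(n_days):
            truth_rows.append(
                {
                    "tag_id": sched.hen_id,
                    "day": day,
                    "date": start_date + dt.timedelta(days=day),
                    "outside_s": daily[day],
                }
            )
    events = pd.DataFrame(
        ev_rows, columns=["date", "time", "tag_id", "direction", "injected"]
    )
    if len(events):
        events = events.sort_values(
            ["tag_id", "date", "time"], kind="stable"
        ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["tag_id", "day", "date", "outside_s"])
    return events, truth


def _event(date: dt.date, t_s: float, tag: str, direction: str, injected: bool) -> dict:
    whole = int(t_s)
    ms = int(round((t_s - whole) * 1000))
    tm = (dt.datetime.combine(date, dt.time()) + dt.timedelta(seconds=whole, milliseconds=ms)).time()
    return {
        "date": date.isoformat(),
        "time": tm.strftime("%H:%M:%S.%f")[:-3],
        "tag_id": tag,
        "direction": direction,
        "injected": injected,
    }
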