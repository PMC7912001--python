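"""RFID pop-hole log parsing, transition pairing and range-use summaries.

Each crossing of a pop-hole antenna is a directional read (``out`` onto
the range, ``in`` back to the pen).  A hen that does not complete a
full transition leaves a "false" unpaired read; pairing is a two-state
machine that forms a visit episode from each out followed by an in,
discards the later of two same-direction reads (first-read-wins), and
discards leading unmatched ``in`` and trailing unmatched ``out`` reads.
Every input event ends up either in an episode or in the discard log.

Daily outside time and the percentage of available days with range
access summarise each hen; hens that never ranged are ``indoor``, hens
with an episode on every available day are ``outdoor``, the rest
``intermediate``.  Selection takes the top outdoor rangers (longest
mean daily outside time) and indoor hens per rearing-treatment cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIRECTIONS = ("out", "in")
CLASSES = ("indoor", "outdoor", "intermediate")


@dataclass
class ParsedLog:
    events: pd.DataFrame     # timestamp, tag_id, direction; sorted per hen
    malformed: pd.DataFrame  # row, reason


@dataclass
class RangingSummary:
    tag_id: str
    daily_outside_s: pd.Series   # indexed by date
    days_accessed: int
    days_available: int
    percent_days: float
    mean_daily_outside_s: float  # mean over available days
    ranging_class: str = field(init=False)

    def __post_init__(self):
        if self.days_accessed == 0:
            self.ranging_class = "indoor"
        elif self.days_accessed == self.days_available:
            self.ranging_class = "outdoor"
        else:
            self.ranging_class = "intermediate"


def parse_log(source) -> ParsedLog:
    """Parse an RFID CSV (date, time, tag_id, direction) or DataFrame.

    Rows with unparseable timestamps are reported in ``malformed``
    rather than silently dropped; an unknown direction value aborts
    with the offending row number.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source, dtype=str)
    required = {"date", "time", "tag_id", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"log missing columns: {sorted(missing)}")
    df = df.reset_index(drop=True)
    bad_dir = ~df["direction"].isin(DIRECTIONS)
    if bad_dir.any():
        row = int(np.flatnonzero(bad_dir)[0])
        raise ValueError(
            f"row {row}: unknown direction {df.loc[row, 'direction']!r} "
            f"(expected one of {DIRECTIONS})"
        )
    ts = pd.to_datetime(
        df["date"].astype(str) + " " + df["time"].astype(str), errors="coerce"
    )
    bad_ts = ts.isna()
    malformed = pd.DataFrame(
        {
            "row": np.flatnonzero(bad_ts),
            "reason": [
                f"unparseable timestamp {df.loc[i, 'date']!r} {df.loc[i, 'time']!r}"
                for i in np.flatnonzero(bad_ts)
            ],
        }
    )
    events = pd.DataFrame(
        {
            "timestamp": ts[~bad_ts],
            "tag_id": df.loc[~bad_ts, "tag_id"].astype(str),
            "direction": df.loc[~bad_ts, "direction"],
        }
    )
    events = events.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(drop=True)
    return ParsedLog(events=events, malformed=malformed)


def pair_transitions(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair one hen's sorted directional reads into visit episodes.

    Returns ``(episodes, discarded)``; conservation holds:
    ``len(events) == 2 * len(episodes) + len(discarded)``.
    """
    ts = events["timestamp"].to_numpy()
    if len(ts) > 1 and (np.diff(ts) < np.timedelta64(0, "ns")).any():
        raise ValueError("events must be time-sorted")
    episodes, discarded = [], []
    outside_since = None
    tag = events["tag_id"].iloc[0] if len(events) else None
    for _, ev in events.iterrows():
        if ev["direction"] == "out":
            if outside_since is None:
                outside_since = ev["timestamp"]
            else:  # repeat out while already outside: later read is false
                discarded.append(
                    {"timestamp": ev["timestamp"], "direction": "out",
                     "reason": "repeated out (incomplete transition)"}
                )
        else:  # "in"
            if outside_since is None:
                discarded.append(
                    {"timestamp": ev["timestamp"], "direction": "in",
                     "reason": "in without prior out"}
                )
            else:
                episodes.append(
                    {
                        "tag_id": tag,
                        "exit_time": outside_since,
                        "entry_time": ev["timestamp"],
                        "duration_s": (ev["timestamp"] - outside_since).total_seconds(),
                    }
                )
                outside_since = None
    if outside_since is not None:
        discarded.append(
            {"timestamp": outside_since, "direction": "out",
             "reason": "trailing out never paired"}
        )
    ep = pd.DataFrame(episodes, columns=["tag_id", "exit_time", "entry_time", "duration_s"])
    dis = pd.DataFrame(discarded, columns=["timestamp", "direction", "reason"])
    return ep, dis


def _daily_totals(episodes: pd.DataFrame, split_midnight: bool = True) -> pd.Series:
    """Per-calendar-date outside seconds, splitting episodes at midnight."""
    totals: dict = {}
    for row in episodes.itertuples():
        start, end = row.exit_time, row.entry_time
        while True:
            day_end = (start + pd.Timedelta(days=1)).normalize()
            if end <= day_end or not split_midnight:
                totals[start.date()] = totals.get(start.date(), 0.0) + (end - start).total_seconds()
                break
            totals[start.date()] = totals.get(start.date(), 0.0) + (day_end - start).total_seconds()
            start = day_end
    return pd.Series(totals, dtype=float).sort_index()


def summarise_ranging(episodes: pd.DataFrame, days_available: int,
                      tag_id: str | None = None,
                      split_midnight: bool = True) -> RangingSummary:
    """Summarise one hen's paired episodes over the observation window."""
    if days_available <= 0:
        raise ValueError("days_available must be > 0")
    if tag_id is None:
        tag_id = episodes["tag_id"].iloc[0] if len(episodes) else "unknown"
    daily = _daily_totals(episodes, split_midnight=split_midnight)
    days_accessed = int((daily > 0).sum())
    return RangingSummary(
        tag_id=tag_id,
        daily_outside_s=daily,
        days_accessed=days_accessed,
        days_available=days_available,
        percent_days=100.0 * days_accessed / days_available,
        mean_daily_outside_s=float(daily.sum()) / days_available,
    )


def summarise_cohort(events: pd.DataFrame, tags: list[str],
                     days_available: int) -> pd.DataFrame:
    """Per-hen summaries for every tag (hens with no events are indoor)."""
    rows = []
    for tag in tags:
        hen_events = events[events["tag_id"] == tag]
        if len(hen_events):
            episodes, _ = pair_transitions(hen_events)
        else:
            episodes = pd.DataFrame(columns=["tag_id", "exit_time", "entry_time", "duration_s"])
        s = summarise_ranging(episodes, days_available, tag_id=tag)
        rows.append(
            {
                "tag_id": tag,
                "days_accessed": s.days_accessed,
                "days_available": s.days_available,
                "percent_days": s.percent_days,
                "mean_daily_outside_s": s.mean_daily_outside_s,
                "ranging_class": s.ranging_class,
            }
        )
    return pd.DataFrame(rows)


def select_hens(summaries: pd.DataFrame, quota: int = 20) -> pd.DataFrame:
    """Select indoor and outdoor hens per rearing-treatment cell.

    ``summaries`` needs ``tag_id, treatment, ranging_class,
    mean_daily_outside_s``.  Outdoor candidates are ranked by mean
    daily outside time descending (the hens that ranged daily and for
    the longest period); indoor candidates come from the never-ranging
    pool.  Ties and the indoor pool order break deterministically by
    tag_id.  A cell short of candidates yields a partial selection with
    a warning.
    """
    selected = []
    for treatment in sorted(summaries["treatment"].unique()):
        for cls in ("indoor", "outdoor"):
            pool = summaries[
                (summaries["treatment"] == treatment)
                & (summaries["ranging_class"] == cls)
            ]
            if cls == "outdoor":
                pool = pool.sort_values(
                    ["mean_daily_outside_s", "tag_id"],
                    ascending=[False, True], kind="stable",
                )
            else:
                pool = pool.sort_values("tag_id", kind="stable")
            if len(pool) < quota:
                warnings.warn(
                    f"cell ({treatment}, {cls}): only {len(pool)} candidates "
                    f"for quota {quota}; partial selection",
                    stacklevel=2,
                )
            selected.append(pool.head(quota))
    return pd.concat(selected, ignore_index=True) if selected else summaries.iloc[0:0]
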