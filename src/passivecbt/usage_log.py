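"""Reading, writing and sessionizing app-usage event logs.

An *event* is one uninterrupted interval of on-app time. Users of
smartphone-delivered therapy tend to interact in bursts — several brief
usages separated by short breaks — so consecutive events whose gap is
strictly shorter than a threshold (60 min by default) are merged into a
single *session*. A session's duration is its summed *active* time, not
the wall-clock span: two 10-min usages with a 5-min break make one
20-min session. Sessions whose active time exceeds an outlier cutoff
(60 min by default) are removed before analysis and returned separately
for audit.

Event and session tables are plain :class:`pandas.DataFrame` objects.
Timestamps are stored timezone-naive in UTC; a per-row ``tz_offset_min``
column carries the participant's local-time offset for calendar-day
arithmetic downstream.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

#: Columns of the on-disk CSV dialect.
USAGE_CSV_COLUMNS = ["participant_id", "start", "end", "tz_offset"]

#: Columns of the in-memory event table.
EVENT_COLUMNS = ["participant_id", "start", "end", "tz_offset_min"]

#: Columns of the in-memory session table.
SESSION_COLUMNS = [
    "participant_id",
    "start",
    "end",
    "active_minutes",
    "n_events",
    "tz_offset_min",
]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

_TZ_RE = re.compile(r"^([+-])(\d{2}):(\d{2})$")

_MINUTE = np.timedelta64(60, "s")


def parse_tz_offset(text: str) -> int:
    """Parse a ``±HH:MM`` timezone offset into minutes east of UTC."""
    m = _TZ_RE.match(text.strip())
    if m is None:
        raise ValueError(f"invalid tz_offset {text!r}; expected ±HH:MM")
    sign = 1 if m.group(1) == "+" else -1
    return sign * (60 * int(m.group(2)) + int(m.group(3)))


def format_tz_offset(minutes: int) -> str:
    sign = "+" if minutes >= 0 else "-"
    minutes = abs(int(minutes))
    return f"{sign}{minutes // 60:02d}:{minutes % 60:02d}"


def _parse_timestamps(raw: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format=TIMESTAMP_FORMAT, errors="coerce")
    bad = parsed.isna() | raw.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(
            f"{path}: malformed {column} timestamp {raw[bad.idxmax()]!r} on line {line}"
        )
    return parsed


def read_usage_log(path) -> pd.DataFrame:
    """Read an app-usage event log CSV into an event table.

    The dialect is comma-separated UTF-8 with header
    ``participant_id,start,end,tz_offset`` and ISO-8601 second-resolution
    timestamps in UTC. A missing ``tz_offset`` column defaults to +00:00.

    Returns events sorted by participant then start time.

    Raises
    ------
    ValueError
        On a malformed row (named by line number), an event with
        ``end <= start``, or overlapping events within a participant
        (the offending pair of lines is reported).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols == USAGE_CSV_COLUMNS[:3]:
        df["tz_offset"] = "+00:00"
    elif cols != USAGE_CSV_COLUMNS:
        raise ValueError(
            f"{path}: unexpected header {cols}; expected {USAGE_CSV_COLUMNS}"
        )
    df["_line"] = np.arange(2, len(df) + 2)

    start = _parse_timestamps(df["start"], path, "start")
    end = _parse_timestamps(df["end"], path, "end")
    try:
        tz = df["tz_offset"].map(parse_tz_offset)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc

    bad = end <= start
    if bad.any():
        line = int(df["_line"][bad].iloc[0])
        raise ValueError(f"{path}: event with end <= start on line {line}")

    events = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "start": start,
            "end": end,
            "tz_offset_min": tz.astype(np.int64),
            "_line": df["_line"],
        }
    ).sort_values(["participant_id", "start"], kind="stable")

    for pid, grp in events.groupby("participant_id", sort=False):
        overlap = grp["start"].values[1:] < grp["end"].values[:-1]
        if overlap.any():
            k = int(np.argmax(overlap))
            a, b = grp["_line"].values[k], grp["_line"].values[k + 1]
            raise ValueError(
                f"{path}: overlapping events for participant {pid!r} "
                f"(lines {a} and {b})"
            )

    return events.drop(columns="_line").reset_index(drop=True)


def write_usage_log(events: pd.DataFrame, path) -> Path:
    """Write an event table in the identical CSV dialect read by
    :func:`read_usage_log`."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "participant_id": events["participant_id"],
            "start": pd.to_datetime(events["start"]).dt.strftime(TIMESTAMP_FORMAT),
            "end": pd.to_datetime(events["end"]).dt.strftime(TIMESTAMP_FORMAT),
            "tz_offset": events["tz_offset_min"].map(format_tz_offset),
        }
    )
    out.to_csv(path, index=False)
    return path


def empty_sessions() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "start": pd.Series(dtype="datetime64[ns]"),
            "end": pd.Series(dtype="datetime64[ns]"),
            "active_minutes": pd.Series(dtype=float),
            "n_events": pd.Series(dtype=np.int64),
            "tz_offset_min": pd.Series(dtype=np.int64),
        }
    )


def merge_into_sessions(events: pd.DataFrame, gap_threshold_min: float = 60.0) -> pd.DataFrame:
    """Merge bursty events into sessions.

    Consecutive events of one participant whose gap (end of one to start
    of the next) is strictly less than ``gap_threshold_min`` belong to the
    same session. A session's ``active_minutes`` is the sum of its
    events' durations; breaks are excluded. Gaps >= the threshold start a
    new session.

    Events must be sorted by (participant, start) and non-overlapping
    within a participant; an empty table yields an empty session table.
    """
    if gap_threshold_min <= 0:
        raise ValueError("gap_threshold_min must be positive")
    if len(events) == 0:
        return empty_sessions()

    frames = []
    for pid, grp in events.groupby("participant_id", sort=True):
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        if np.any(start[1:] < start[:-1]):
            raise ValueError(f"events for participant {pid!r} are not sorted by start")
        if np.any(start[1:] < end[:-1]):
            raise ValueError(f"events for participant {pid!r} overlap")

        gaps_min = (start[1:] - end[:-1]) / _MINUTE
        dur_min = (end - start) / _MINUTE
        n = len(grp)
        # first event index of each session, then reduce over the blocks
        firsts = np.concatenate(([0], 1 + np.nonzero(gaps_min >= gap_threshold_min)[0]))
        lasts = np.concatenate((firsts[1:] - 1, [n - 1]))
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "start": start[firsts],
                    "end": end[lasts],
                    "active_minutes": np.add.reduceat(dur_min, firsts),
                    "n_events": lasts - firsts + 1,
                    "tz_offset_min": grp["tz_offset_min"].to_numpy()[firsts],
                }
            )
        )

    return pd.concat(frames, ignore_index=True)[SESSION_COLUMNS]


def filter_outlier_sessions(
    sessions: pd.DataFrame, max_active_min: float = 60.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sessions into (kept, removed) by the outlier cutoff.

    Sessions with ``active_minutes`` strictly greater than
    ``max_active_min`` are removed; a session of exactly the cutoff is
    kept. Order is preserved in both outputs.
    """
    if max_active_min < 0:
        raise ValueError("max_active_min must be non-negative")
    if len(sessions) == 0:
        return sessions.copy(), sessions.copy()
    mask = sessions["active_minutes"] > max_active_min
    return (
        sessions.loc[~mask].reset_index(drop=True),
        sessions.loc[mask].reset_index(drop=True),
    )


def sessionize(
    events: pd.DataFrame,
    gap_threshold_min: float = 60.0,
    max_active_min: float = 60.0,
) -> pd.DataFrame:
    """Merge events into sessions and drop outliers; returns kept sessions.

    Burst merging happens before outlier removal, so a long stretch of
    short usages separated by short breaks can itself be removed as an
    outlier if its summed active time exceeds the cutoff.
    """
    kept, _ = filter_outlier_sessions(
        merge_into_sessions(events, gap_threshold_min), max_active_min
    )
    return kept
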