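"""Shared builders and independent oracles used across the test suite."""

from datetime import date

import numpy as np
import pandas as pd

T0 = pd.Timestamp("2019-01-07")
TSTART = date(2019, 1, 7)


def events_from_minutes(intervals, pid="p1", tz=0):
    """Event table from (start_min, end_min) pairs relative to T0."""
    rows = [
        {
            "participant_id": pid,
            "start": T0 + pd.Timedelta(minutes=float(s)),
            "end": T0 + pd.Timedelta(minutes=float(e)),
            "tz_offset_min": np.int64(tz),
        }
        for s, e in intervals
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "start", "end", "tz_offset_min"]
    )


def sessions_from_minutes(triples, pid="p1", tz=0):
    """Session table from (start_min, end_min, active_min) triples."""
    rows = [
        {
            "participant_id": pid,
            "start": T0 + pd.Timedelta(minutes=float(s)),
            "end": T0 + pd.Timedelta(minutes=float(e)),
            "active_minutes": float(a),
            "n_events": 1,
            "tz_offset_min": np.int64(tz),
        }
        for s, e, a in triples
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "start",
            "end",
            "active_minutes",
            "n_events",
            "tz_offset_min",
        ],
    )


def fixes_from_minutes(points, pid="p1", tz=0):
    """GPS fix table from (minute, lat, lon) triples relative to T0."""
    rows = [
        {
            "participant_id": pid,
            "timestamp": T0 + pd.Timedelta(minutes=float(m)),
            "lat": float(lat),
            "lon": float(lon),
            "tz_offset_min": np.int64(tz),
        }
        for m, lat, lon in points
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "timestamp", "lat", "lon", "tz_offset_min"]
    )


def stays_from_minutes(rows, pid="p1", tz=0):
    """Stay table from (location_id, start_min, end_min) triples."""
    out = [
        {
            "participant_id": pid,
            "location_id": lid,
            "start": T0 + pd.Timedelta(minutes=float(s)),
            "end": T0 + pd.Timedelta(minutes=float(e)),
            "dwell_min": float(e) - float(s),
            "tz_offset_min": np.int64(tz),
        }
        for lid, s, e in rows
    ]
    return pd.DataFrame(
        out,
        columns=["participant_id", "location_id", "start", "end", "dwell_min", "tz_offset_min"],
    )


def brute_force_merge(intervals, gap_threshold):
    """O(n^2) pairwise-closure oracle for burst merging.

    Repeatedly merges any two blocks whose boundary gap is strictly less
    than the threshold until a fixed point; returns sorted
    (start, end, active, n_events) tuples in minutes.
    """
    items = [[float(s), float(e), float(e - s), 1] for s, e in sorted(intervals)]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(len(items)):
                if i == j:
                    continue
                a, b = items[i], items[j]
                gap = b[0] - a[1] if a[0] <= b[0] else a[0] - b[1]
                if gap < gap_threshold:
                    merged = [
                        min(a[0], b[0]),
                        max(a[1], b[1]),
                        a[2] + b[2],
                        a[3] + b[3],
                    ]
                    items = [it for k, it in enumerate(items) if k not in (i, j)]
                    items.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(it) for it in items)


def sessions_to_tuples(sessions):
    """Sessions as (start_min, end_min, active, n_events) tuples for oracles."""
    out = []
    for r in sessions.itertuples(index=False):
        s = (pd.Timestamp(r.start) - T0).total_seconds() / 60.0
        e = (pd.Timestamp(r.end) - T0).total_seconds() / 60.0
        out.append((s, e, float(r.active_minutes), int(r.n_events)))
    return sorted(out)
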