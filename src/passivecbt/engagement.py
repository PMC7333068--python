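"""Per-participant engagement features over treatment windows.

Two engagement constructs drive the downstream statistics:

* **Quantity of use** — total session active minutes in a window.
* **Frequency of use** — the mean gap (end of one session to the start
  of the next) between consecutive sessions, in minutes. Gap
  distributions are heavy-tailed, so analyses use the natural log of the
  per-participant mean gap.

Also provided: days-used counts, a session-duration histogram with the
standard bins (0,5], (5,10], (10,20], (20,40], (40,inf) minutes, and the
per-day usage series behind longitudinal engagement plots.

A session belongs to a window when its *start* falls inside the window;
sessions are never split across window boundaries. Calendar days are
participant-local (via ``tz_offset_min``).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable

import numpy as np
import pandas as pd

_MINUTE = np.timedelta64(60, "s")
_DAY = np.timedelta64(86400, "s")

#: Session-duration histogram bin edges in active minutes (right-closed).
DURATION_BIN_EDGES = (0.0, 5.0, 10.0, 20.0, 40.0, np.inf)
DURATION_BIN_LABELS = ("le5", "5_10", "10_20", "20_40", "gt40")

FEATURE_CSV_COLUMNS = [
    "participant_id",
    "window",
    "quantity_min",
    "mean_gap_min",
    "log_mean_gap",
    "days_used",
    "bin_le5",
    "bin_5_10",
    "bin_10_20",
    "bin_20_40",
    "bin_gt40",
]


@dataclass(frozen=True)
class TreatmentWindow:
    """Half-open range of day indices [start_day, end_day) from treatment start."""

    label: str
    start_day: int
    end_day: int

    def __post_init__(self):
        if self.end_day <= self.start_day:
            raise ValueError("end_day must exceed start_day")
        if self.start_day < 0:
            raise ValueError("start_day must be >= 0")

    @classmethod
    def first_half(cls) -> "TreatmentWindow":
        """The first six weeks of a 12-week program: days [0, 42)."""
        return cls("first_half", 0, 42)

    @classmethod
    def full(cls) -> "TreatmentWindow":
        """The full 12-week program: days [0, 84)."""
        return cls("full", 0, 84)

    @classmethod
    def custom(cls, start_day: int, end_day: int) -> "TreatmentWindow":
        return cls("custom", start_day, end_day)

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day


def local_day_index(
    timestamps: pd.Series | np.ndarray,
    tz_offset_min: pd.Series | np.ndarray | int,
    treatment_start: date,
) -> np.ndarray:
    """Participant-local day index of each timestamp, day 0 = treatment start."""
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps))).to_numpy()
    off = np.asarray(tz_offset_min, dtype=np.int64) * _MINUTE
    origin = np.datetime64(pd.Timestamp(treatment_start))
    return ((ts + off - origin) // _DAY).astype(np.int64)


def _in_window(sessions: pd.DataFrame, window: TreatmentWindow, treatment_start: date):
    day = local_day_index(
        sessions["start"], sessions["tz_offset_min"].to_numpy(), treatment_start
    )
    return (day >= window.start_day) & (day < window.end_day), day


def quantity_of_use(
    sessions: pd.DataFrame, window: TreatmentWindow, treatment_start: date
) -> float:
    """Total active minutes of sessions starting inside the window."""
    if len(sessions) == 0:
        return 0.0
    mask, _ = _in_window(sessions, window, treatment_start)
    return float(sessions.loc[mask, "active_minutes"].sum())


def frequency_of_use(
    sessions: pd.DataFrame, window: TreatmentWindow, treatment_start: date
) -> tuple[float, float]:
    """(mean gap, ln mean gap) between consecutive sessions in the window.

    The gap runs from the end of one session to the start of the next.
    With fewer than two in-window sessions the value is undefined and
    ``(nan, nan)`` is returned; such participants are excluded from
    frequency analyses rather than raising.
    """
    if len(sessions) == 0:
        return (float("nan"), float("nan"))
    mask, _ = _in_window(sessions, window, treatment_start)
    sub = sessions.loc[mask].sort_values("start")
    if len(sub) < 2:
        return (float("nan"), float("nan"))
    gaps = (sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]) / _MINUTE
    mean_gap = float(np.mean(gaps))
    if mean_gap <= 0:
        return mean_gap, float("nan")
    return mean_gap, float(np.log(mean_gap))


def days_used(
    sessions: pd.DataFrame, window: TreatmentWindow, treatment_start: date
) -> int:
    """Distinct participant-local calendar days containing >= 1 session start."""
    if len(sessions) == 0:
        return 0
    mask, day = _in_window(sessions, window, treatment_start)
    return int(np.unique(day[mask]).size)


def duration_histogram(sessions: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of session active durations over the standard bins.

    Returns ``(counts, percentages)`` where percentages are rounded to one
    decimal place and are zero for an empty input. Bins are left-open and
    right-closed, so a 5.0-min session lands in the first bin.
    """
    edges = np.asarray(DURATION_BIN_EDGES)
    if len(sessions) == 0:
        z = np.zeros(len(edges) - 1)
        return z.astype(np.int64), z
    d = sessions["active_minutes"].to_numpy()
    idx = np.searchsorted(edges[1:-1], d, side="left")  # right-closed bins
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(np.int64)
    pct = np.round(100.0 * counts / counts.sum(), 1)
    return counts, pct


def daily_usage_series(
    sessions: pd.DataFrame, window: TreatmentWindow, treatment_start: date
) -> np.ndarray:
    """Per-day total active minutes over the window (zero-filled).

    Index 0 corresponds to ``window.start_day``; a session contributes
    its full active time to the day it starts on.
    """
    out = np.zeros(window.n_days)
    if len(sessions) == 0:
        return out
    mask, day = _in_window(sessions, window, treatment_start)
    np.add.at(
        out,
        day[mask] - window.start_day,
        sessions.loc[mask, "active_minutes"].to_numpy(),
    )
    return out


@dataclass
class EngagementFeatures:
    participant_id: str
    window: str
    quantity_min: float
    mean_gap_min: float  # nan when < 2 sessions
    log_mean_gap: float  # nan when < 2 sessions
    days_used: int
    histogram: tuple  # counts per duration bin


def compute_engagement(
    sessions: pd.DataFrame,
    window: TreatmentWindow,
    treatment_start: date,
    participant_id: str,
) -> EngagementFeatures:
    """All engagement features for one participant over one window."""
    mean_gap, log_gap = frequency_of_use(sessions, window, treatment_start)
    mask = (
        _in_window(sessions, window, treatment_start)[0]
        if len(sessions)
        else np.zeros(0, dtype=bool)
    )
    counts, _ = duration_histogram(sessions.loc[mask] if len(sessions) else sessions)
    return EngagementFeatures(
        participant_id=participant_id,
        window=window.label,
        quantity_min=quantity_of_use(sessions, window, treatment_start),
        mean_gap_min=mean_gap,
        log_mean_gap=log_gap,
        days_used=days_used(sessions, window, treatment_start),
        histogram=tuple(int(c) for c in counts),
    )


def features_frame(features: Iterable[EngagementFeatures]) -> pd.DataFrame:
    """Tabulate features in the engagement CSV layout."""
    rows = []
    for f in features:
        row = {
            "participant_id": f.participant_id,
            "window": f.window,
            "quantity_min": f.quantity_min,
            "mean_gap_min": f.mean_gap_min,
            "log_mean_gap": f.log_mean_gap,
            "days_used": f.days_used,
        }
        row.update(
            {f"bin_{lab}": c for lab, c in zip(DURATION_BIN_LABELS, f.histogram)}
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS)
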