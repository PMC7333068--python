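"""GPS mobility features: stay detection, home inference, time at home.

Raw GPS fixes (participant, timestamp, lat, lon) are reduced to
anonymized *stay intervals*: maximal runs of consecutive fixes within a
small radius (100 m default) whose time span reaches a dwell threshold
(30 min default). Stays at the same true place receive the same opaque
random identifier (``ID78``-style) and no coordinates survive into any
downstream table — the mapping from identifier back to place is never
exported.

*Home* is the location identifier with the greatest overlap with the
nightly 03:00-06:00 local window. The share of labeled stay time spent
at home inside a +/-3-day window around a clinical assessment is the
candidate passive marker of avoidance fed to the outcome statistics;
all remaining location identifiers count as outside of home.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from datetime import date
from math import asin, cos, radians, sin, sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engagement import local_day_index
from .usage_log import TIMESTAMP_FORMAT, format_tz_offset, parse_tz_offset

GPS_CSV_COLUMNS = ["participant_id", "timestamp", "lat", "lon", "tz_offset"]
FIX_COLUMNS = ["participant_id", "timestamp", "lat", "lon", "tz_offset_min"]
STAY_COLUMNS = ["participant_id", "location_id", "start", "end", "dwell_min", "tz_offset_min"]
STAY_CSV_COLUMNS = ["participant_id", "location_id", "start", "end", "dwell_min"]

_EARTH_RADIUS_M = 6371008.8
_MINUTE = np.timedelta64(60, "s")

#: Default nightly window (start hour, end hour) used for home inference.
NIGHT_WINDOW = (3, 6)


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between WGS84 points (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def _haversine_scalar(lat1, lon1, lat2, lon2) -> float:
    # math-library version: much faster than numpy for single pairs
    lat1, lon1, lat2, lon2 = map(radians, (lat1, lon1, lat2, lon2))
    a = sin((lat2 - lat1) / 2) ** 2 + cos(lat1) * cos(lat2) * sin((lon2 - lon1) / 2) ** 2
    return 2 * _EARTH_RADIUS_M * asin(sqrt(a))


def read_gps_log(path) -> pd.DataFrame:
    """Read a GPS fix log CSV (``participant_id,timestamp,lat,lon,tz_offset``).

    Fixes are returned sorted by participant and timestamp; coordinates
    are validated against WGS84 ranges.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "tz_offset": str})
    cols = list(df.columns)
    if cols == GPS_CSV_COLUMNS[:4]:
        df["tz_offset"] = "+00:00"
    elif cols != GPS_CSV_COLUMNS:
        raise ValueError(f"{path}: unexpected header {cols}; expected {GPS_CSV_COLUMNS}")
    ts = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT, errors="coerce")
    if ts.isna().any():
        line = int(ts.isna().idxmax()) + 2
        raise ValueError(f"{path}: malformed timestamp on line {line}")
    fixes = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "timestamp": ts,
            "lat": df["lat"].astype(float),
            "lon": df["lon"].astype(float),
            "tz_offset_min": df["tz_offset"].map(parse_tz_offset).astype(np.int64),
        }
    ).sort_values(["participant_id", "timestamp"], kind="stable")
    _check_coordinates(fixes["lat"].to_numpy(), fixes["lon"].to_numpy())
    return fixes.reset_index(drop=True)


def write_gps_log(fixes: pd.DataFrame, path) -> Path:
    path = Path(path)
    if len(fixes) == 0:
        out = pd.DataFrame(columns=GPS_CSV_COLUMNS)
    else:
        out = pd.DataFrame(
            {
                "participant_id": fixes["participant_id"],
                "timestamp": pd.to_datetime(fixes["timestamp"]).dt.strftime(TIMESTAMP_FORMAT),
                "lat": fixes["lat"],
                "lon": fixes["lon"],
                "tz_offset": fixes["tz_offset_min"].map(format_tz_offset),
            }
        )
    out.to_csv(path, index=False)
    return path


def write_stays(stays: pd.DataFrame, path) -> Path:
    """Write the anonymized stay table (no coordinate columns, by construction)."""
    path = Path(path)
    if len(stays) == 0:
        out = pd.DataFrame(columns=STAY_CSV_COLUMNS)
    else:
        out = pd.DataFrame(
            {
                "participant_id": stays["participant_id"],
                "location_id": stays["location_id"],
                "start": pd.to_datetime(stays["start"]).dt.strftime(TIMESTAMP_FORMAT),
                "end": pd.to_datetime(stays["end"]).dt.strftime(TIMESTAMP_FORMAT),
                "dwell_min": stays["dwell_min"],
            }
        )
    out.to_csv(path, index=False)
    return path


def _check_coordinates(lat: np.ndarray, lon: np.ndarray) -> None:
    if len(lat) and (np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180)):
        raise ValueError("coordinates outside WGS84 range")


def detect_stays(
    fixes: pd.DataFrame,
    radius_m: float = 100.0,
    dwell_min: float = 30.0,
    max_gap_min: float | None = 60.0,
) -> pd.DataFrame:
    """Cluster time-ordered fixes into raw stay clusters with centroids.

    A cluster is a maximal run of consecutive fixes all within
    ``radius_m`` (great-circle) of the run's *first* fix; runs spanning
    at least ``dwell_min`` minutes become stays, shorter runs are
    discarded as transit. Anchoring on the first fix keeps the procedure
    deterministic and single-pass.

    A run is additionally split whenever consecutive fixes are more than
    ``max_gap_min`` minutes apart (``None`` disables): with whole days of
    GPS commonly missing, an evening fix would otherwise join a
    morning-after-next fix into one multi-day "stay", silently counting
    unobserved time as dwell. Dwell is only claimed across gaps short
    relative to the 15-min sampling cadence.

    Returns a frame with columns ``participant_id, start, end, dwell_min,
    centroid_lat, centroid_lon, tz_offset_min`` — an intermediate product
    still carrying coordinates; see :func:`anonymize_stays`.
    """
    rows = []
    gap_cap = math.inf if max_gap_min is None else float(max_gap_min)
    for pid, grp in fixes.groupby("participant_id", sort=True):
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        _check_coordinates(lat, lon)
        t = grp["timestamp"].to_numpy()
        t_min = t.astype("datetime64[s]").astype(np.int64) / 60.0
        tz = grp["tz_offset_min"].to_numpy()
        latl, lonl = lat.tolist(), lon.tolist()
        n = len(grp)
        i = 0
        while i < n:
            lat0, lon0 = latl[i], lonl[i]
            j = i + 1
            while j < n:
                if t_min[j] - t_min[j - 1] > gap_cap:
                    break
                if latl[j] == lat0 and lonl[j] == lon0:
                    j += 1
                elif _haversine_scalar(lat0, lon0, latl[j], lonl[j]) <= radius_m:
                    j += 1
                else:
                    break
            span = t_min[j - 1] - t_min[i]
            if span >= dwell_min:
                rows.append(
                    (
                        pid,
                        t[i],
                        t[j - 1],
                        float(span),
                        float(np.mean(lat[i:j])),
                        float(np.mean(lon[i:j])),
                        int(tz[i]),
                    )
                )
            i = j
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "start",
            "end",
            "dwell_min",
            "centroid_lat",
            "centroid_lon",
            "tz_offset_min",
        ],
    )


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    key = int.from_bytes(hashlib.sha256(participant_id.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def anonymize_stays(
    clusters: pd.DataFrame, seed: int, radius_m: float = 100.0
) -> pd.DataFrame:
    """Replace stay-cluster centroids with opaque random location identifiers.

    Clusters whose centroids lie within ``radius_m`` of an
    already-labeled place reuse its identifier; new places draw a fresh
    random ``ID<number>`` label. The centroid-to-identifier mapping is
    internal and intentionally not returned: the output carries no
    coordinates.
    """
    out_rows = []
    for pid, grp in clusters.groupby("participant_id", sort=True):
        rng = _participant_rng(seed, pid)
        pool = rng.permutation(np.arange(10, 10_000))
        reps: list[tuple[float, float, str]] = []
        for row in grp.itertuples(index=False):
            loc_id = None
            for rlat, rlon, rid in reps:
                if _haversine_scalar(row.centroid_lat, row.centroid_lon, rlat, rlon) <= radius_m:
                    loc_id = rid
                    break
            if loc_id is None:
                loc_id = f"ID{pool[len(reps)]}"
                reps.append((row.centroid_lat, row.centroid_lon, loc_id))
            out_rows.append((pid, loc_id, row.start, row.end, row.dwell_min, row.tz_offset_min))
    return pd.DataFrame(out_rows, columns=STAY_COLUMNS)


@dataclass
class HomeModel:
    participant_id: str
    home_location_id: str | None
    n_night_observations: int


def _night_overlap_minutes(
    start_local: pd.Timestamp, end_local: pd.Timestamp, night: tuple[int, int]
) -> tuple[float, int]:
    """Total minutes and distinct nights of overlap with the nightly window."""
    total = 0.0
    nights = 0
    day = start_local.normalize()
    while day <= end_local.normalize():
        w0 = day + pd.Timedelta(hours=night[0])
        w1 = day + pd.Timedelta(hours=night[1])
        ov = (min(end_local, w1) - max(start_local, w0)).total_seconds() / 60.0
        if ov > 0:
            total += ov
            nights += 1
        day += pd.Timedelta(days=1)
    return total, nights


def infer_home(stays: pd.DataFrame, night: tuple[int, int] = NIGHT_WINDOW) -> HomeModel:
    """Infer the home location of one participant from anonymized stays.

    Home is the location identifier with the greatest total overlap, in
    minutes, with the daily 03:00-06:00 participant-local window; absent
    when no stay touches any night window. Exact ties break toward the
    earliest-observed identifier.
    """
    pids = stays["participant_id"].unique()
    if len(pids) > 1:
        raise ValueError("infer_home expects stays for a single participant")
    pid = str(pids[0]) if len(pids) else ""
    minutes: dict[str, float] = {}
    nights: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for k, row in enumerate(stays.sort_values("start").itertuples(index=False)):
        off = pd.Timedelta(minutes=int(row.tz_offset_min))
        ov, nn = _night_overlap_minutes(
            pd.Timestamp(row.start) + off, pd.Timestamp(row.end) + off, night
        )
        if ov > 0:
            minutes[row.location_id] = minutes.get(row.location_id, 0.0) + ov
            nights[row.location_id] = nights.get(row.location_id, 0) + nn
            first_seen.setdefault(row.location_id, k)
    if not minutes:
        return HomeModel(pid, None, 0)
    home = min(minutes, key=lambda lid: (-minutes[lid], first_seen[lid]))
    return HomeModel(pid, home, nights[home])


def assessment_window(
    assessment_day: int, window_days: int = 3, treatment_start_day: int = 0
) -> tuple[int, int]:
    """Inclusive day-index window around a clinical assessment.

    The window covers ``window_days`` before, the day itself, and
    ``window_days`` after, truncated at treatment start — GPS is
    generally unavailable before the app is installed, so a baseline
    assessment on day 0 yields days 0-3 only.
    """
    return (max(assessment_day - window_days, treatment_start_day), assessment_day + window_days)


@dataclass
class MobilityFeatures:
    participant_id: str
    phase: str
    pct_time_at_home: float  # nan when no labeled stay time in window
    observed_minutes: float
    missing_days: int


def _local_minutes(ts, tz_offset_min, treatment_start: date) -> np.ndarray:
    """Participant-local minutes since local midnight of treatment day 0."""
    ts = pd.to_datetime(pd.Series(np.asarray(ts))).to_numpy()
    off = np.asarray(tz_offset_min, dtype=np.int64) * _MINUTE
    origin = np.datetime64(pd.Timestamp(treatment_start))
    return (ts + off - origin) / _MINUTE


def percent_time_at_home(
    stays: pd.DataFrame,
    home: HomeModel,
    window: tuple[int, int],
    treatment_start: date,
    phase: str = "custom",
    fixes: pd.DataFrame | None = None,
) -> MobilityFeatures:
    """Share of labeled stay time spent at home within a day window.

    ``window`` is an inclusive (first_day, last_day) pair of day indices.
    The denominator is labeled stay time only: transit and unlabeled
    (<30-min) time is excluded, mirroring the home/outside dichotomy of
    the location identifiers. The feature is absent (nan) when the home
    is unknown or no stay time falls inside the window.

    ``missing_days`` counts window days without a single GPS fix when
    ``fixes`` is supplied.
    """
    lo_min = window[0] * 1440.0
    hi_min = (window[1] + 1) * 1440.0
    missing = 0
    if fixes is not None:
        day = local_day_index(
            fixes["timestamp"], fixes["tz_offset_min"].to_numpy(), treatment_start
        ) if len(fixes) else np.zeros(0, dtype=np.int64)
        present = set(int(d) for d in np.unique(day))
        missing = sum(1 for d in range(window[0], window[1] + 1) if d not in present)

    if home.home_location_id is None or len(stays) == 0:
        return MobilityFeatures(home.participant_id, phase, float("nan"), 0.0, missing)

    s = _local_minutes(stays["start"], stays["tz_offset_min"].to_numpy(), treatment_start)
    e = _local_minutes(stays["end"], stays["tz_offset_min"].to_numpy(), treatment_start)
    ov = np.clip(np.minimum(e, hi_min) - np.maximum(s, lo_min), 0.0, None)
    total = float(ov.sum())
    if total == 0.0:
        return MobilityFeatures(home.participant_id, phase, float("nan"), 0.0, missing)
    at_home = float(ov[(stays["location_id"] == home.home_location_id).to_numpy()].sum())
    return MobilityFeatures(
        home.participant_id, phase, 100.0 * at_home / total, total, missing
    )


DEFAULT_PHASE_BINS = ((0, 56), (56, 70), (70, 84))


def app_use_context_minutes(
    sessions: pd.DataFrame,
    stays: pd.DataFrame,
    home: HomeModel,
    treatment_start: date,
    phase_bins: Sequence[tuple[int, int]] = DEFAULT_PHASE_BINS,
) -> list[tuple[float, float]]:
    """Per-phase (home-overlap, any-stay-overlap) session minutes.

    The building block of :func:`app_use_location_context`; exposing the
    raw minutes lets callers pool numerators and denominators across a
    cohort before taking the ratio.
    """
    out: list[tuple[float, float]] = []
    if home.home_location_id is None or len(stays) == 0 or len(sessions) == 0:
        return [(0.0, 0.0)] * len(phase_bins)

    st = stays.sort_values("start")
    s_start = _local_minutes(st["start"], st["tz_offset_min"].to_numpy(), treatment_start)
    s_end = _local_minutes(st["end"], st["tz_offset_min"].to_numpy(), treatment_start)
    is_home = (st["location_id"] == home.home_location_id).to_numpy()

    a = _local_minutes(sessions["start"], sessions["tz_offset_min"].to_numpy(), treatment_start)
    b = _local_minutes(sessions["end"], sessions["tz_offset_min"].to_numpy(), treatment_start)
    day = (a // 1440).astype(np.int64)

    for lo, hi in phase_bins:
        in_phase = (day >= lo) & (day < hi)
        num = den = 0.0
        for k in np.nonzero(in_phase)[0]:
            i0 = int(np.searchsorted(s_end, a[k], side="right"))
            i1 = int(np.searchsorted(s_start, b[k], side="left"))
            for m in range(i0, i1):
                ov = min(b[k], s_end[m]) - max(a[k], s_start[m])
                if ov > 0:
                    den += ov
                    if is_home[m]:
                        num += ov
        out.append((num, den))
    return out


def app_use_location_context(
    sessions: pd.DataFrame,
    stays: pd.DataFrame,
    home: HomeModel,
    treatment_start: date,
    phase_bins: Sequence[tuple[int, int]] = DEFAULT_PHASE_BINS,
) -> list[float]:
    """Per-phase share of app-session time spent at home.

    For each phase (default: weeks 1-8, 9-10, 11-12 as day ranges), the
    percentage of session wall-clock time overlapping a *home* stay among
    session time overlapping *any* stay. Session time with no concurrent
    stay (transit, missing GPS days) contributes to neither numerator nor
    denominator; a phase with no overlapping stay time is nan.
    """
    minutes = app_use_context_minutes(sessions, stays, home, treatment_start, phase_bins)
    return [100.0 * num / den if den > 0 else float("nan") for num, den in minutes]


def gps_missingness(
    fixes: pd.DataFrame,
    treatment_start: date,
    n_days: int,
    start_day: int = 0,
) -> tuple[int, float]:
    """Count study days with zero GPS fixes.

    Returns ``(missing_days, fraction)`` over the ``n_days`` study days
    starting at ``start_day``; a day is missing iff it contains no fix.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if len(fixes) == 0:
        return n_days, 1.0
    day = local_day_index(
        fixes["timestamp"], fixes["tz_offset_min"].to_numpy(), treatment_start
    )
    present = np.unique(day)
    present = present[(present >= start_day) & (present < start_day + n_days)]
    missing = n_days - present.size
    return int(missing), missing / n_days
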