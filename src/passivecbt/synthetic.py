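"""Synthetic cohorts for a 12-week smartphone-CBT study.

No raw data from the pilot study is distributed, so this module
generates complete observable cohorts — app-usage event logs, GPS fix
traces, and three clinician severity assessments per participant — with
the statistical structure the analysis pipeline assumes:

* bursty, short app usages (lognormal active durations with a ~3-min
  median, most sessions <= 5 min) whose daily rate declines linearly
  across the 12 weeks;
* a latent per-participant usage-frequency trait jointly drawn with
  treatment improvement at a configurable correlation (default -0.6
  between log mean gap and percent improvement);
* home-anchored mobility — home occupied every night, daytime away
  excursions whose extent is coupled to concurrent severity so that
  percent time at home correlates with severity at a configurable level
  (default +0.5) — sampled every 15 min with ~60% of days missing;
* app use shifting from home to outside across treatment
  (70% / 57% / 17% at home by phase).

Ground truth (latent traits, planted targets, true home coordinates) is
retained separately from the observable tables and written to a clearly
named sidecar file that the analysis pipeline never reads.

All randomness flows from the single config seed through per-participant
``SeedSequence`` spawn keys, so regenerating with the same config is
byte-identical and adding participants leaves earlier participants'
random streams untouched.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import mobility as mb
from . import outcomes as oc
from . import usage_log as ul

_SECOND = np.timedelta64(1, "s")


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort; defaults mirror the study conditions."""

    n_participants: int = 10
    treatment_days: int = 84
    seed: int = 0

    # app-usage process
    session_rate_start: float = 3.0  # sessions/day at day 0
    session_rate_end: float = 0.5  # sessions/day at the last day
    duration_log_mean: float = math.log(3.0)  # lognormal active minutes
    duration_log_sd: float = 0.82
    burst_prob: float = 0.3  # session emitted as 2-3 raw events

    # planted effects
    rho_freq_improve: float = -0.6  # corr(log mean gap, % improvement)
    rho_home_severity: float = 0.5  # corr(% time at home, severity)
    log_gap_sd: float = 0.7  # between-participant SD of latent log gap

    # mobility / GPS observation model
    gps_day_missingness: float = 0.60
    gps_interval_min: int = 15
    n_away_locations: int = 3
    home_use_schedule: tuple = (0.70, 0.57, 0.17)
    phase_day_bins: tuple = ((0, 56), (56, 70), (70, 84))
    pct_home_mean: float = 65.0  # marginal mean of window % time at home
    pct_home_sd: float = 9.0  # marginal SD (signal + noise)

    # clinical trajectories
    baseline_ybocs_mean: float = 30.0
    baseline_ybocs_sd: float = 4.0
    improvement_mean: float = 45.3  # percent, posttreatment
    improvement_sd: float = 14.7

    tz_offset_min: int = 0
    treatment_start: date = date(2019, 1, 7)

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.treatment_days < 14:
            raise ValueError("treatment_days must be >= 14")
        for name in ("burst_prob", "gps_day_missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for p in self.home_use_schedule:
            if not 0.0 <= p <= 1.0:
                raise ValueError("home_use_schedule probabilities must be in [0, 1]")
        for name in ("rho_freq_improve", "rho_home_severity"):
            if not abs(getattr(self, name)) < 1.0:
                raise ValueError(f"|{name}| must be < 1")
        if self.session_rate_start <= 0 or self.session_rate_end <= 0:
            raise ValueError("session rates must be positive")
        if self.gps_interval_min <= 0:
            raise ValueError("gps_interval_min must be positive")

    @property
    def assessment_days(self) -> tuple[int, int, int]:
        return (0, self.treatment_days // 2, self.treatment_days)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    usage_events: pd.DataFrame
    gps_fixes: pd.DataFrame
    assessments: pd.DataFrame
    truth: dict = field(repr=False)


def _rng(seed: int, participant_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(participant_index, stream))
    )


def _phase_of_day(day: int, bins) -> int:
    for k, (lo, hi) in enumerate(bins):
        if lo <= day < hi:
            return k
    return len(bins) - 1


def _draw_latents(cfg: CohortConfig, rng: np.random.Generator):
    """Jointly draw improvement and the usage-frequency latent."""
    e = rng.standard_normal(2)
    z1 = e[0]
    rho = cfg.rho_freq_improve
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * e[1]
    improvement = cfg.improvement_mean + cfg.improvement_sd * z1
    return improvement, z2


def _draw_baseline(cfg: CohortConfig, rng: np.random.Generator) -> int:
    # truncated to the eligibility range (> 20, within scale maximum)
    for _ in range(1000):
        b = int(round(rng.normal(cfg.baseline_ybocs_mean, cfg.baseline_ybocs_sd)))
        if 20 < b <= oc.YBOCS_MAX:
            return b
    raise RuntimeError("could not draw an eligible baseline severity")


def _recorded_scores(cfg, rng, baseline: int, improvement: float) -> np.ndarray:
    D = cfg.treatment_days
    days = np.array(cfg.assessment_days, dtype=float)
    true = baseline * (1.0 - improvement / 100.0 * days / D)
    noise = rng.integers(-1, 2, size=3)
    return np.clip(np.round(true).astype(int) + noise, 0, oc.YBOCS_MAX)


def _draw_sessions(cfg: CohortConfig, rng: np.random.Generator, z2: float):
    """Daily session counts, active durations and burst decomposition.

    Returns a list of ``(day, active_min, event_durs, break_durs)`` with
    start times not yet assigned. The per-participant rate multiplier
    ``exp(-log_gap_sd * z2)`` turns the shared declining daily intensity
    into participant-specific mean gaps whose log is (approximately)
    linear in the latent trait.
    """
    D = cfg.treatment_days
    mult = math.exp(-cfg.log_gap_sd * z2)
    d = np.arange(D)
    lam = (
        cfg.session_rate_start
        + (cfg.session_rate_end - cfg.session_rate_start) * d / max(D - 1, 1)
    ) * mult
    counts = rng.poisson(lam)
    K = int(counts.sum())
    day_of = np.repeat(d, counts)
    active = rng.lognormal(cfg.duration_log_mean, cfg.duration_log_sd, K)

    burst = rng.random(K) < cfg.burst_prob
    k_events = np.ones(K, dtype=int)
    k_events[burst] = rng.integers(2, 4, size=int(burst.sum()))
    # batched burst decomposition draws
    i2 = np.nonzero(k_events == 2)[0]
    i3 = np.nonzero(k_events == 3)[0]
    u2 = rng.uniform(0.3, 0.7, size=i2.size)
    g3 = rng.gamma(2.0, size=(i3.size, 3))
    g3 = g3 / g3.sum(axis=1, keepdims=True)
    br2 = rng.uniform(2.0, 15.0, size=(i2.size, 1))
    br3 = rng.uniform(2.0, 15.0, size=(i3.size, 2))

    props = {int(k): np.array([1.0]) for k in np.nonzero(k_events == 1)[0]}
    breaks = {int(k): np.zeros(0) for k in np.nonzero(k_events == 1)[0]}
    for row, k in enumerate(i2):
        props[int(k)] = np.array([u2[row], 1.0 - u2[row]])
        breaks[int(k)] = br2[row]
    for row, k in enumerate(i3):
        props[int(k)] = g3[row]
        breaks[int(k)] = br3[row]

    sessions = []
    for k in range(K):
        sessions.append(
            (int(day_of[k]), float(active[k]), active[k] * props[k], breaks[k])
        )
    return sessions, mult


def _mobility_schedule(cfg, rng, recorded, s_bar, beta, eps_sd):
    """Per-day away-excursion minutes realizing the planted home-severity link.

    Days inside a +/-3-day assessment window share one target percent
    time at home derived from the *recorded* severity at that assessment
    (the exact value the pipeline later correlates against); other days
    use the linearly interpolated severity with fresh daily noise.
    """
    D = cfg.treatment_days
    n_days = D + 4  # cover the posttreatment assessment window
    days = np.arange(n_days)
    sev = np.interp(days, np.array(cfg.assessment_days, dtype=float), recorded.astype(float))

    eps_daily = rng.normal(0.0, eps_sd, size=n_days)
    pct = np.clip(cfg.pct_home_mean + beta * (sev - s_bar) + eps_daily, 5.0, 100.0)

    eps_w = rng.normal(0.0, eps_sd, size=3)
    pct_targets = np.clip(
        cfg.pct_home_mean + beta * (recorded.astype(float) - s_bar) + eps_w, 5.0, 100.0
    )
    for k, a in enumerate(cfg.assessment_days):
        lo, hi = mb.assessment_window(a)
        pct[lo : min(hi, n_days - 1) + 1] = pct_targets[k]

    away = np.clip((1.0 - pct / 100.0) * 1440.0, 0.0, 900.0)
    away[away < 30.0] = 0.0  # too short to register as a labeled place
    away_start = 420.0 + rng.random(n_days) * (900.0 - away)  # within 07:00-22:00
    away_loc = rng.integers(0, cfg.n_away_locations, size=n_days)
    missing = rng.random(n_days) < cfg.gps_day_missingness
    return {
        "n_days": n_days,
        "away": away,
        "away_start": away_start,
        "away_loc": away_loc,
        "missing": missing,
        "pct_targets": pct_targets,
    }


def _emit_fixes(cfg, sched, home_lat, home_lon, away_lat, away_lon):
    """GPS fixes every ``gps_interval_min`` on observed days (local minutes)."""
    grid = np.arange(0, 1440, cfg.gps_interval_min, dtype=float)
    obs = np.nonzero(~sched["missing"])[0]
    if obs.size == 0:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    a0 = sched["away_start"][obs][:, None]
    aw = sched["away"][obs][:, None]
    away_mask = (grid[None, :] >= a0) & (grid[None, :] < a0 + aw)
    loc = sched["away_loc"][obs]
    lat = np.where(away_mask, away_lat[loc][:, None], home_lat)
    lon = np.where(away_mask, away_lon[loc][:, None], home_lon)
    mins = obs[:, None] * 1440.0 + grid[None, :]
    return mins.ravel(), lat.ravel(), lon.ravel()


def _place_sessions(cfg, rng, sessions, sched, with_gps: bool):
    """Assign each session a start minute, at home or away per the phase schedule."""
    placed = []
    for day, active, ev_durs, br_durs in sessions:
        span = float(active + br_durs.sum())
        phase = _phase_of_day(day, cfg.phase_day_bins)
        at_home = rng.random() < cfg.home_use_schedule[phase]
        start = None
        if with_gps:
            a0 = float(sched["away_start"][day])
            aw = float(sched["away"][day])
            if not at_home and aw >= span + 2.0:
                start = a0 + rng.random() * (aw - span - 1.0)
            else:
                blocks = [(0.0, a0), (a0 + aw, 1440.0)]
                usable = [(lo, hi - lo - span - 1.0) for lo, hi in blocks if hi - lo > span + 1.0]
                if usable:
                    weights = np.array([u[1] for u in usable])
                    pick = usable[int(rng.choice(len(usable), p=weights / weights.sum()))]
                    start = pick[0] + rng.random() * pick[1]
        if start is None:
            start = rng.random() * max(1440.0 - span - 1.0, 1.0)
        placed.append((day * 1440.0 + start, ev_durs, br_durs))
    placed.sort(key=lambda s: s[0])

    # resolve rare collisions by pushing a session past its predecessor
    events = []
    prev_end = -1.0
    for start, ev_durs, br_durs in placed:
        if start <= prev_end:
            start = prev_end + 1.0
        t = start
        for k, dur in enumerate(ev_durs):
            events.append((t, t + dur))
            t += dur
            if k < len(br_durs):
                t += br_durs[k]
        prev_end = t
    return events


def generate_cohort(
    config: CohortConfig, with_usage: bool = True, with_gps: bool = True
) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    ``with_usage`` / ``with_gps`` restrict generation to the requested
    data streams (useful for focused simulation studies); assessments
    are always produced. Identical arguments always regenerate an
    identical cohort.
    """
    cfg = config
    origin = np.datetime64(pd.Timestamp(cfg.treatment_start))
    tz = cfg.tz_offset_min

    pids = [f"P{i + 1:03d}" for i in range(cfg.n_participants)]
    per = []
    for i in range(cfg.n_participants):
        rng0 = _rng(cfg.seed, i, 0)
        improvement, z2 = _draw_latents(cfg, rng0)
        baseline = _draw_baseline(cfg, rng0)
        recorded = _recorded_scores(cfg, rng0, baseline, improvement)
        sessions, mult = (
            _draw_sessions(cfg, _rng(cfg.seed, i, 1), z2) if with_usage else ([], float("nan"))
        )
        per.append(
            {"improvement": improvement, "z2": z2, "recorded": recorded, "sessions": sessions, "mult": mult}
        )

    # cohort-level calibration of the severity -> home-time coupling
    pooled = np.concatenate([p["recorded"] for p in per]).astype(float)
    s_bar = float(pooled.mean())
    s_sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    rho = cfg.rho_home_severity
    beta = rho * cfg.pct_home_sd / s_sd if s_sd > 0 else 0.0
    eps_sd = cfg.pct_home_sd * math.sqrt(1.0 - rho * rho)

    usage_rows = []
    fix_arrays = []
    assess_rows = []
    truth = {"participants": {}}
    for i, (pid, p) in enumerate(zip(pids, per)):
        rng2 = _rng(cfg.seed, i, 2)
        home_lat = 42.0 + 0.002 * i
        home_lon = -71.0
        away_lat = home_lat + 0.012 * (1 + np.arange(cfg.n_away_locations))
        away_lon = home_lon + 0.012 * (1 + np.arange(cfg.n_away_locations))

        sched = None
        if with_gps:
            sched = _mobility_schedule(cfg, rng2, p["recorded"], s_bar, beta, eps_sd)
            mins, lat, lon = _emit_fixes(cfg, sched, home_lat, home_lon, away_lat, away_lon)
            if mins.size:
                ts = origin + ((mins - tz) * 60.0).astype(np.int64) * _SECOND
                fix_arrays.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "timestamp": ts,
                            "lat": lat,
                            "lon": lon,
                            "tz_offset_min": np.int64(tz),
                        }
                    )
                )

        if with_usage and p["sessions"]:
            for t0, t1 in _place_sessions(cfg, rng2, p["sessions"], sched, with_gps):
                usage_rows.append(
                    (
                        pid,
                        origin + np.int64(round((t0 - tz) * 60.0)) * _SECOND,
                        origin + np.int64(round((t1 - tz) * 60.0)) * _SECOND,
                        tz,
                    )
                )

        for phase, day, score in zip(oc.PHASES, cfg.assessment_days, p["recorded"]):
            assess_rows.append((pid, phase, int(day), int(score)))

        truth["participants"][pid] = {
            "improvement_true": p["improvement"],
            "rate_multiplier": p["mult"],
            "latent_log_gap": cfg.log_gap_sd * p["z2"],
            "recorded_ybocs": [int(s) for s in p["recorded"]],
            "home_lat": home_lat,
            "home_lon": home_lon,
            "pct_home_targets": [float(x) for x in sched["pct_targets"]] if sched else None,
            "n_missing_gps_days": int(sched["missing"].sum()) if sched else None,
        }
    truth["coupling"] = {"beta": beta, "eps_sd": eps_sd, "severity_pooled_sd": s_sd}

    usage_events = pd.DataFrame(
        usage_rows, columns=["participant_id", "start", "end", "tz_offset_min"]
    )
    if len(usage_events):
        usage_events = usage_events.sort_values(["participant_id", "start"]).reset_index(drop=True)
    gps_fixes = (
        pd.concat(fix_arrays, ignore_index=True)
        if fix_arrays
        else pd.DataFrame(columns=mb.FIX_COLUMNS)
    )
    assessments = pd.DataFrame(assess_rows, columns=oc.ASSESSMENT_CSV_COLUMNS)
    return SyntheticCohort(cfg, usage_events, gps_fixes, assessments, truth)


#: File names written by :func:`write_cohort`. The ground-truth sidecar is
#: synthetic-only bookkeeping and is never read by the analysis pipeline.
USAGE_FILE = "usage.csv"
GPS_FILE = "gps.csv"
ASSESSMENTS_FILE = "assessments.csv"
GROUND_TRUTH_FILE = "ground_truth_synthetic.json"


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the observable cohort files plus the ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    usage = cohort.usage_events
    if len(usage) == 0:
        usage = pd.DataFrame(
            {
                "participant_id": pd.Series(dtype=str),
                "start": pd.Series(dtype="datetime64[ns]"),
                "end": pd.Series(dtype="datetime64[ns]"),
                "tz_offset_min": pd.Series(dtype=np.int64),
            }
        )
    paths = {
        "usage": ul.write_usage_log(usage, directory / USAGE_FILE),
        "gps": mb.write_gps_log(cohort.gps_fixes, directory / GPS_FILE),
    }
    cohort.assessments.to_csv(directory / ASSESSMENTS_FILE, index=False)
    paths["assessments"] = directory / ASSESSMENTS_FILE

    cfg = dataclasses.asdict(cohort.config)
    cfg["treatment_start"] = cohort.config.treatment_start.isoformat()
    payload = {"config": cfg, "truth": cohort.truth}
    gt = directory / GROUND_TRUTH_FILE
    gt.write_text(json.dumps(payload, indent=2, sort_keys=True))
    paths["ground_truth"] = gt
    return paths
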