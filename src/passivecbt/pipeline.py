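"""End-to-end orchestration: ingest, sessionize, features, statistics, report.

:func:`run_pipeline` consumes a cohort directory containing the three
dialect files (``usage.csv``, ``gps.csv``, ``assessments.csv``) and
produces a report bundle:

* ``report.json`` — every statistic with its inputs' provenance, the
  seeds used, and per-participant exclusion logs;
* ``table1.csv`` — descriptive means/SDs of improvement, quantity and
  (log) frequency with their correlations against improvement;
* ``daily_usage.csv`` — the participant-by-day active-minutes matrix;
* ``severity_home_pairs.csv`` — pooled severity / percent-time-at-home
  pairs;
* ``engagement.csv`` and ``stays.csv`` — per-participant feature and
  anonymized stay exports.

Analyses degrade gracefully: a participant with fewer than two sessions
is excluded from frequency analyses with a logged reason, a participant
without an inferable home is excluded from mobility analyses, and a
statistic whose preconditions fail is reported as unavailable rather
than aborting the run.
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
import yaml

from . import engagement as eng
from . import mobility as mb
from . import outcomes as oc
from . import usage_log as ul
from .synthetic import ASSESSMENTS_FILE, GPS_FILE, USAGE_FILE

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Tunable thresholds of a pipeline run; defaults are the study's."""

    input_dir: Path = Path(".")
    output_dir: Path = Path("out")
    gap_threshold_min: float = 60.0
    outlier_max_min: float = 60.0
    stay_radius_m: float = 100.0
    dwell_min: float = 30.0
    max_fix_gap_min: float = 60.0
    night_window: tuple = mb.NIGHT_WINDOW
    assessment_window_days: int = 3
    resample_iterations: int = 6000
    seed: int = 0
    improvement_scale: str = "percent"  # or "proportion"
    treatment_days: int = 84
    treatment_start: date = date(2019, 1, 7)
    phase_bins: tuple = mb.DEFAULT_PHASE_BINS

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        for name in ("gap_threshold_min", "outlier_max_min", "stay_radius_m", "dwell_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.assessment_window_days < 0:
            raise ValueError("assessment_window_days must be >= 0")
        if self.improvement_scale not in ("percent", "proportion"):
            raise ValueError("improvement_scale must be 'percent' or 'proportion'")
        if isinstance(self.treatment_start, str):
            self.treatment_start = date.fromisoformat(self.treatment_start)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key:value config file (YAML-compatible)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat key: value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        if "night_window" in raw:
            raw["night_window"] = tuple(raw["night_window"])
        if "phase_bins" in raw:
            raw["phase_bins"] = tuple(tuple(b) for b in raw["phase_bins"])
        return cls(**raw)


def _nan_to_none(obj):
    """Recursively replace non-finite floats so the report is strict JSON."""
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if math.isfinite(obj) else None
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _corr_or_reason(x, y) -> dict:
    try:
        res = oc.correlate(x, y)
        return {"r": res.r, "p_value": res.p_value, "n": res.n, "reason": None}
    except ValueError as exc:
        return {"r": None, "p_value": None, "n": None, "reason": str(exc)}


@dataclass
class _Participant:
    pid: str
    sessions: pd.DataFrame
    n_outliers_removed: int
    full: eng.EngagementFeatures
    first_half: eng.EngagementFeatures
    improvement: float
    ybocs: dict
    pct_home: dict = field(default_factory=dict)
    home_found: bool = False
    missing_fraction: float = float("nan")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the report as a dict (also serialized to
    ``output_dir/report.json``). Raises ``FileNotFoundError`` when an
    input file is absent.
    """
    cfg = config
    for name in (USAGE_FILE, GPS_FILE, ASSESSMENTS_FILE):
        if not (cfg.input_dir / name).exists():
            raise FileNotFoundError(f"missing input file: {cfg.input_dir / name}")

    events = ul.read_usage_log(cfg.input_dir / USAGE_FILE)
    fixes = mb.read_gps_log(cfg.input_dir / GPS_FILE)
    assessments = oc.read_assessments(cfg.input_dir / ASSESSMENTS_FILE)

    D = cfg.treatment_days
    w_full = eng.TreatmentWindow("full", 0, D)
    w_half = eng.TreatmentWindow("first_half", 0, D // 2)
    study_days = D + cfg.assessment_window_days + 1  # through the post window

    participants = sorted(assessments["participant_id"].unique())
    exclusions: dict[str, list] = {"frequency": [], "mobility": [], "improvement": []}
    per: list[_Participant] = []
    stay_frames = []
    context_minutes = np.zeros((len(cfg.phase_bins), 2))
    daily = {}

    for pid in participants:
        ev = events[events["participant_id"] == pid]
        merged = ul.merge_into_sessions(ev, cfg.gap_threshold_min)
        sessions, removed = ul.filter_outlier_sessions(merged, cfg.outlier_max_min)

        full = eng.compute_engagement(sessions, w_full, cfg.treatment_start, pid)
        half = eng.compute_engagement(sessions, w_half, cfg.treatment_start, pid)
        daily[pid] = eng.daily_usage_series(sessions, w_full, cfg.treatment_start)
        if not math.isfinite(full.log_mean_gap):
            exclusions["frequency"].append(
                {"participant_id": pid, "reason": "fewer than 2 sessions in window"}
            )

        arows = assessments[assessments["participant_id"] == pid]
        ybocs = {r.phase: int(r.ybocs_total) for r in arows.itertuples(index=False)}
        adays = {r.phase: int(r.day) for r in arows.itertuples(index=False)}
        if "baseline" in ybocs and "posttreatment" in ybocs and ybocs["baseline"] > 0:
            improvement = oc.percent_improvement(ybocs["baseline"], ybocs["posttreatment"])
            if cfg.improvement_scale == "proportion":
                improvement /= 100.0
        else:
            improvement = float("nan")
            exclusions["improvement"].append(
                {"participant_id": pid, "reason": "missing baseline or posttreatment score"}
            )

        p = _Participant(
            pid, sessions, len(removed), full, half, improvement, ybocs
        )

        fx = fixes[fixes["participant_id"] == pid]
        clusters = mb.detect_stays(fx, cfg.stay_radius_m, cfg.dwell_min, cfg.max_fix_gap_min)
        stays = mb.anonymize_stays(clusters, cfg.seed, cfg.stay_radius_m)
        if len(stays):
            stay_frames.append(stays)
        home = (
            mb.infer_home(stays, cfg.night_window)
            if len(stays)
            else mb.HomeModel(pid, None, 0)
        )
        p.home_found = home.home_location_id is not None
        if not p.home_found:
            exclusions["mobility"].append(
                {"participant_id": pid, "reason": "no inferable home location"}
            )
        for phase, day in adays.items():
            window = mb.assessment_window(day, cfg.assessment_window_days)
            feat = mb.percent_time_at_home(
                stays, home, window, cfg.treatment_start, phase=phase, fixes=fx
            )
            p.pct_home[phase] = feat
        p.missing_fraction = mb.gps_missingness(fx, cfg.treatment_start, study_days)[1]

        for k, (num, den) in enumerate(
            mb.app_use_context_minutes(sessions, stays, home, cfg.treatment_start, cfg.phase_bins)
        ):
            context_minutes[k, 0] += num
            context_minutes[k, 1] += den
        per.append(p)

    # ---- cohort-level statistics -------------------------------------
    improvement = np.array([p.improvement for p in per])
    quantity = np.array([p.full.quantity_min for p in per])
    mean_gap = np.array([p.full.mean_gap_min for p in per])
    log_gap = np.array([p.full.log_mean_gap for p in per])

    def _screen(values):
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        try:
            s = oc.normality_screen(x)
            return {"statistic": s.statistic, "p_value": s.p_value, "recommend_log": s.recommend_log}
        except ValueError as exc:
            return {"statistic": None, "p_value": None, "recommend_log": None, "reason": str(exc)}

    corr_quantity = _corr_or_reason(quantity, improvement)
    corr_frequency = _corr_or_reason(log_gap, improvement)

    try:
        reg = oc.regress_improvement(improvement, quantity, log_gap)
        regression = {
            "n": reg.n,
            "r_squared": reg.r_squared,
            "predictors": {
                k: dataclasses.asdict(v) for k, v in reg.predictors.items()
            },
            "reason": None,
        }
    except ValueError as exc:
        regression = {"n": None, "r_squared": None, "predictors": None, "reason": str(exc)}

    Y = np.array([[p.ybocs.get(ph, np.nan) for ph in oc.PHASES] for p in per], dtype=float)
    H = np.array(
        [
            [
                p.pct_home[ph].pct_time_at_home if ph in p.pct_home else np.nan
                for ph in oc.PHASES
            ]
            for p in per
        ],
        dtype=float,
    )
    severity_home = _corr_or_reason(Y.ravel(), H.ravel())

    resample = oc.resample_single_timepoint(
        Y, H, n_iter=cfg.resample_iterations, seed=cfg.seed
    ) if len(per) else None

    mean_ybocs = np.nanmean(Y, axis=1) if len(per) else np.zeros(0)
    missing_fracs = np.array([p.missing_fraction for p in per])
    missingness_corr = _corr_or_reason(missing_fracs, mean_ybocs)

    counts, pct = eng.duration_histogram(
        pd.concat([p.sessions for p in per]) if per else ul.empty_sessions()
    )

    at_home_pct = [
        100.0 * num / den if den > 0 else None for num, den in context_minutes
    ]

    analyzed_frequency = sum(1 for p in per if math.isfinite(p.full.log_mean_gap))
    analyzed_mobility = sum(1 for p in per if p.home_found)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        # analysis parameters only; deployment paths are not provenance
        "config": {
            k: (str(v) if isinstance(v, (Path, date)) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("input_dir", "output_dir")
        },
        "n_participants": len(per),
        "engagement": {
            "per_participant": [
                {
                    "participant_id": p.pid,
                    "quantity_min_full": p.full.quantity_min,
                    "quantity_min_first_half": p.first_half.quantity_min,
                    "mean_gap_min_full": p.full.mean_gap_min,
                    "log_mean_gap_full": p.full.log_mean_gap,
                    "mean_gap_min_first_half": p.first_half.mean_gap_min,
                    "log_mean_gap_first_half": p.first_half.log_mean_gap,
                    "days_used_full": p.full.days_used,
                    "n_outlier_sessions_removed": p.n_outliers_removed,
                }
                for p in per
            ],
            "duration_histogram": {
                "bins": list(eng.DURATION_BIN_LABELS),
                "counts": [int(c) for c in counts],
                "percentages": [float(x) for x in pct],
            },
            "at_home_use_pct_by_phase": at_home_pct,
            "normality": {"quantity": _screen(quantity), "mean_gap": _screen(mean_gap)},
        },
        "correlations": {
            "quantity_vs_improvement": corr_quantity,
            "log_frequency_vs_improvement": corr_frequency,
            "severity_vs_pct_time_at_home": severity_home,
            "missingness_vs_severity": missingness_corr,
        },
        "regression": regression,
        "resample": (
            {
                "n_iterations": resample.n_iterations,
                "median_r": resample.median_r,
                "n_absent": resample.n_absent,
                "seed": resample.seed,
            }
            if resample
            else None
        ),
        "gps_missingness": {
            "per_participant_fraction": {
                p.pid: p.missing_fraction for p in per
            },
            "mean_fraction": float(np.nanmean(missing_fracs)) if len(per) else None,
        },
        "exclusions": exclusions,
        "counts": {
            "input_participants": len(per),
            "analyzed_frequency": analyzed_frequency,
            "excluded_frequency": len(exclusions["frequency"]),
            "analyzed_mobility": analyzed_mobility,
            "excluded_mobility": len(exclusions["mobility"]),
        },
    }

    _write_outputs(cfg, report, per, daily, Y, H, stay_frames, improvement, quantity, log_gap)
    return report


def _mean_sd(x) -> tuple:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return (float("nan"), float("nan"))
    return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else float("nan")


def _write_outputs(cfg, report, per, daily, Y, H, stay_frames, improvement, quantity, log_gap):
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "report.json", "w") as fh:
        json.dump(_nan_to_none(report), fh, indent=2, sort_keys=True)
        fh.write("\n")

    # Table-1-shaped summary: midtreatment = first-half window
    imp_mid = [
        oc.percent_improvement(p.ybocs["baseline"], p.ybocs["midpoint"])
        if {"baseline", "midpoint"} <= set(p.ybocs) and p.ybocs["baseline"] > 0
        else float("nan")
        for p in per
    ]
    rows = []
    for label, mid_vals, post_vals, corr_key in (
        ("percent_improvement", imp_mid, improvement, None),
        ("quantity_of_use_min", [p.first_half.quantity_min for p in per], quantity, "quantity_vs_improvement"),
        ("log_frequency_of_use", [p.first_half.log_mean_gap for p in per], log_gap, "log_frequency_vs_improvement"),
    ):
        m_mean, m_sd = _mean_sd(mid_vals)
        p_mean, p_sd = _mean_sd(post_vals)
        corr = report["correlations"][corr_key] if corr_key else {"r": None, "p_value": None}
        rows.append(
            {
                "variable": label,
                "mid_mean": m_mean,
                "mid_sd": m_sd,
                "post_mean": p_mean,
                "post_sd": p_sd,
                "r_with_improvement": corr["r"],
                "p_value": corr["p_value"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "table1.csv", index=False)

    mat = pd.DataFrame(daily).T
    mat.index.name = "participant_id"
    mat.columns = [f"day_{d}" for d in range(mat.shape[1])]
    mat.to_csv(out / "daily_usage.csv")

    pairs = []
    for i, p in enumerate(per):
        for k, ph in enumerate(oc.PHASES):
            pairs.append(
                {
                    "participant_id": p.pid,
                    "phase": ph,
                    "ybocs_total": Y[i, k] if np.isfinite(Y[i, k]) else "",
                    "pct_time_at_home": H[i, k] if np.isfinite(H[i, k]) else "",
                }
            )
    pd.DataFrame(pairs).to_csv(out / "severity_home_pairs.csv", index=False)

    feats = [p.full for p in per] + [p.first_half for p in per]
    eng.features_frame(feats).to_csv(out / "engagement.csv", index=False)

    stays = pd.concat(stay_frames, ignore_index=True) if stay_frames else pd.DataFrame(columns=mb.STAY_COLUMNS)
    mb.write_stays(stays, out / "stays.csv")
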