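"""Outcome statistics for engagement and mobility features.

The primary clinical outcome is percent improvement on the BDD-YBOCS, a
clinician-rated 0-48 severity scale:
``100 * (baseline - posttreatment) / baseline``. Engagement features
(quantity, log mean gap) are related to improvement by Pearson
correlation and a two-predictor OLS regression; the time-at-home marker
is related to concurrent absolute severity on pooled
participant-by-phase pairs.

Because each participant contributes three severity/home-time pairs, a
resampling robustness check repeatedly (6000x by default) draws a single
time point per participant and recomputes the correlation; a median
resampled r close to the pooled r argues the pooled estimate is not an
artifact of the longitudinal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

ASSESSMENT_CSV_COLUMNS = ["participant_id", "phase", "day", "ybocs_total"]
PHASES = ("baseline", "midpoint", "posttreatment")

#: Condition-number threshold above which the regression design is
#: declared collinear.
COLLINEARITY_CONDITION_LIMIT = 1e8

YBOCS_MAX = 48


def read_assessments(path) -> pd.DataFrame:
    """Read the assessment CSV (``participant_id,phase,day,ybocs_total``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "phase": str})
    if list(df.columns) != ASSESSMENT_CSV_COLUMNS:
        raise ValueError(
            f"{path}: unexpected header {list(df.columns)}; expected {ASSESSMENT_CSV_COLUMNS}"
        )
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        raise ValueError(f"{path}: unknown phase {df['phase'][bad_phase].iloc[0]!r}")
    scores = df["ybocs_total"].astype(int)
    if ((scores < 0) | (scores > YBOCS_MAX)).any():
        raise ValueError(f"{path}: ybocs_total outside [0, {YBOCS_MAX}]")
    df["ybocs_total"] = scores
    df["day"] = df["day"].astype(int)
    return df


def percent_improvement(baseline: float, post: float) -> float:
    """Percent improvement from baseline to posttreatment severity.

    ``100 * (baseline - post) / baseline``; negative when symptoms
    worsen. A non-positive baseline is an error (the scale has no
    meaningful percent change from zero).
    """
    if baseline <= 0:
        raise ValueError("baseline severity must be positive")
    return 100.0 * (baseline - post) / baseline


@dataclass
class NormalityScreen:
    statistic: float
    p_value: float
    recommend_log: bool


def normality_screen(values, alpha: float = 0.05) -> NormalityScreen:
    """Shapiro-Wilk screen with a log-transform recommendation.

    A log transform is recommended when normality is rejected
    (p < ``alpha``), all values are positive, and the sample is
    right-skewed — the long-tail pattern typical of between-session gap
    times.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality screen requires n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    w, p = stats.shapiro(x)
    recommend = bool(p < alpha and np.all(x > 0) and stats.skew(x) > 0)
    return NormalityScreen(float(w), float(p), recommend)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value.

    Pairs with a missing (nan) member are dropped listwise; fewer than
    three complete pairs or a constant input is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation requires n >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))


@dataclass
class PredictorEstimate:
    beta: float
    ci95_low: float
    ci95_high: float
    p_value: float


@dataclass
class RegressionResult:
    predictors: dict[str, PredictorEstimate]
    n: int
    r_squared: float


def regress_improvement(
    y, x1, x2, names: tuple[str, str] = ("quantity", "log_frequency")
) -> RegressionResult:
    """OLS of improvement on quantity and log frequency of use.

    Ordinary least squares with intercept; per-predictor coefficient,
    t-based 95% CI and two-sided p. Rows with any missing value are
    dropped listwise. Collinear predictors (design condition number above
    :data:`COLLINEARITY_CONDITION_LIMIT`) raise, naming the pair.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[keep], x1[keep], x2[keep]
    n = y.size
    if n < 4:  # intercept + 2 predictors + 1
        raise ValueError("regression requires n > number of predictors + 1")
    X = np.column_stack([x1, x2])
    # condition number of the standardized design: scale-free collinearity check
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor in regression design")
    if np.linalg.cond((X - X.mean(axis=0)) / sd) > COLLINEARITY_CONDITION_LIMIT:
        raise ValueError(f"collinear predictors: {names[0]} and {names[1]}")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    ci = fit.conf_int(alpha=0.05)
    predictors = {}
    for k, name in enumerate(names, start=1):
        predictors[name] = PredictorEstimate(
            beta=float(fit.params[k]),
            ci95_low=float(ci[k, 0]),
            ci95_high=float(ci[k, 1]),
            p_value=float(fit.pvalues[k]),
        )
    return RegressionResult(predictors=predictors, n=int(n), r_squared=float(fit.rsquared))


@dataclass
class ResampleResult:
    n_iterations: int
    r_values: np.ndarray = field(repr=False)  # nan where an iteration was unusable
    median_r: float
    n_absent: int
    seed: int


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0:
        return float("nan")
    return float((xm @ ym) / denom)


def resample_single_timepoint(
    ybocs: np.ndarray,
    home_pct: np.ndarray,
    n_iter: int = 6000,
    seed: int = 0,
) -> ResampleResult:
    """Single-timepoint resampling robustness check.

    ``ybocs`` and ``home_pct`` are (n_participants, 3) arrays of severity
    scores and concurrent percent-time-at-home at baseline, midpoint and
    posttreatment (nan where a pair is missing). Each iteration draws one
    of the three time points per participant uniformly, drops
    participants whose drawn pair is incomplete, and records the Pearson
    r of the remaining pairs. Iterations with fewer than three usable
    pairs (or a degenerate constant draw) are recorded as absent (nan)
    and counted separately. Fully reproducible given the seed.
    """
    Y = np.asarray(ybocs, dtype=float)
    H = np.asarray(home_pct, dtype=float)
    if Y.shape != H.shape or Y.ndim != 2 or Y.shape[1] != 3:
        raise ValueError("expected matching (n_participants, 3) arrays")
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 3, size=(n_iter, n))
    rows = np.arange(n)
    r_values = np.full(n_iter, np.nan)
    for it in range(n_iter):
        y = Y[rows, draws[it]]
        h = H[rows, draws[it]]
        keep = np.isfinite(y) & np.isfinite(h)
        if keep.sum() >= 3:
            r_values[it] = _pearson_r(y[keep], h[keep])
    valid = np.isfinite(r_values)
    median_r = float(np.median(r_values[valid])) if valid.any() else float("nan")
    return ResampleResult(
        n_iterations=int(n_iter),
        r_values=r_values,
        median_r=median_r,
        n_absent=int(n_iter - valid.sum()),
        seed=int(seed),
    )


def severity_home_correlation(ybocs: np.ndarray, home_pct: np.ndarray) -> CorrelationResult:
    """Pooled correlation of absolute severity with percent time at home.

    Inputs are (n_participants, 3) arrays (or already-pooled vectors);
    pairs are pooled across phases so each participant contributes up to
    three observations.
    """
    return correlate(np.ravel(ybocs), np.ravel(home_pct))


def missingness_severity_check(missing_fractions, ybocs_scores) -> CorrelationResult:
    """Correlate per-participant GPS missing-day fractions with severity.

    A near-zero correlation supports treating GPS missingness as random
    with respect to symptoms.
    """
    return correlate(missing_fractions, ybocs_scores)
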