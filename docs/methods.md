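# Methods

This note documents the models and procedures implemented in
`passivecbt`, the defaults and why they were chosen, the numerical
choices that matter, and the limits of what the synthetic benchmark can
show.

## Sessionization of app-usage logs

An app-usage log is a set of non-overlapping intervals of on-app time
per participant. Smartphone therapy use is *bursty*: several brief
usages separated by short breaks form one psychological "sitting".
Burst merging therefore joins consecutive events whose end-to-start gap
is **strictly less than 60 min** (configurable) into one session, and a
session's duration is its **summed active time**, not its wall-clock
span — two 10-min usages with a 5-min break are one 20-min session.
Sessions with **active time > 60 min** are removed as outliers: even a
sequence of longer exercises (an audio exercise, coach messages, an
exposure task) rarely exceeds an hour of genuine use, and longer
records usually mean the app was left open.

Ordering matters and is fixed as **merge first, filter second**. This
makes the 20-min worked example and the cutoff mutually consistent: a
burst of short usages is first assembled into its session, and only the
assembled session is judged against the cutoff. The cutoff boundary is
"greater than" (a 60.0-min session is kept); both the gap threshold and
the cutoff are parameters of `merge_into_sessions` /
`filter_outlier_sessions`.

Properties guaranteed (and tested): merging conserves total active
minutes; raising the gap threshold never increases the session count;
the output equals an O(n²) pairwise-closure oracle on exhaustive small
inputs with gaps probing the boundary (1, 59, 60, 61, 120 min).

## Engagement features

* **Quantity of use** — total active minutes of sessions *starting*
  inside a treatment window. Windows are half-open day-index ranges
  ([0, 42) for the first half, [0, 84) for the full 12 weeks); sessions
  are never split across a boundary.
* **Frequency of use** — mean end-to-start gap between consecutive
  in-window sessions, in minutes. Gap distributions are heavy-tailed,
  so analyses use the **natural log of the per-participant mean gap**
  (log of mean, not mean of logs). The base-e choice is checkable
  against the published pairing of non-transformed and transformed
  means: ln 512 = 6.24 and ln 626 = 6.44 at two decimals. Participants
  with fewer than two in-window sessions get an absent value and are
  excluded from frequency analyses (logged, not an error).
* **Days used** — distinct participant-local calendar days with at
  least one session start. Calendar arithmetic uses the per-row
  timezone offset, because "a day of app use" is a human-local notion.
* **Duration histogram** — bins (0,5], (5,10], (10,20], (20,40],
  (40,∞) active minutes, right-closed so a 5.0-min session is in the
  first bin ("≤ 5 min").
* **Daily usage series** — per-day total active minutes, zero-filled;
  its sum equals quantity of use by construction (tested).

## Mobility features

**Stay detection** reduces a fix stream to dwell episodes. The
literature offers many stay-point algorithms; since only the two
thresholds (100 m radius, 30 min dwell) are scientifically meaningful
here, the simplest deterministic single-pass rule consistent with them
is used: a maximal run of consecutive fixes all within 100 m
(haversine great-circle) of the run's *first* fix becomes a stay if its
time span reaches 30 min; shorter runs are transit. A run is
additionally **split when consecutive fixes are more than
`max_gap_min` = 60 min apart**. This cap is essential under day-level
missingness: without it, an evening fix joins the next observed
morning's fix — possibly days later — into one "stay", silently
claiming unobserved time as home dwell (and, empirically, biasing
percent time at home upward by 15–25 points). Sixty minutes is four
missed beats of the 15-min sampling cadence.

**Anonymization** maps stay centroids within 100 m of each other to one
opaque random identifier (`ID78`-style) per participant; coordinates do
not appear in any downstream table and the mapping is never exported.
Identifier draws come from a participant-keyed seeded generator, so a
permutation of the input yields a bijective relabeling.

**Home inference** picks the identifier with the greatest total overlap
minutes with the daily 03:00–06:00 local window (overlap minutes rather
than stay counts break most ties naturally; residual exact ties go to
the earliest-observed identifier). Home is absent when no stay touches
any night window.

**Percent time at home** is computed in an inclusive ±3-day window
around each assessment day, truncated at treatment start (GPS does not
exist before the app is installed, so the baseline window is days 0–3).
The denominator is **labeled stay time only**: transit and sub-30-min
stops are excluded, mirroring the home/outside dichotomy of the
location labels. The feature is absent exactly when no labeled stay
time falls in the window.

**App-use location context** assigns session wall-clock time to
home/away by overlap with concurrent stays, per phase (defaults: weeks
1–8, 9–10, 11–12). Session time with no concurrent stay (missing days,
transit) is excluded from numerator and denominator.

**GPS missingness** is day-level: a study day with zero fixes is
missing. Study days run from treatment start through the end of the
posttreatment assessment window.

## Outcome statistics

Percent improvement is `100·(baseline − post)/baseline` on the 0–100
scale (a proportion scale is available via `improvement_scale`).
Normality screening is Shapiro-Wilk with a log-transform recommendation
when normality is rejected for an all-positive, right-skewed sample.
Correlations are Pearson with two-sided p (the frequency variable is
log-transformed to meet normality; rank alternatives were deliberately
not made the default). The regression is OLS with intercept and
t-based 95% CIs, with a scale-free condition-number check (limit 1e8)
that names the collinear pair; listwise deletion throughout, with
deletions logged in the report.

The **single-timepoint resampling check** draws, per iteration, one of
the three assessment-linked (severity, % time at home) pairs per
participant uniformly at random, drops incomplete pairs, and records
the Pearson r; 6000 iterations by default from one seeded
`numpy.random.Generator`, the seed echoed in the output. Iterations
with fewer than three usable pairs (or a degenerate constant draw) are
recorded as absent and counted. If the median resampled r is close to
the pooled 3-points-per-participant r, the pooled estimate is not an
artifact of the repeated-measures structure. With identical triples per
participant every iteration returns the same value and the median
equals it exactly; it agrees with the pooled r computed on the
triplicated pairs to numerical precision (~1e-15), the residual being
float summation order.

The missingness check pairs each participant's overall missing-day
fraction with their mean severity across the three assessments; a
near-zero correlation supports treating GPS missingness as ignorable
with respect to symptoms.

## Synthetic cohort generator

The generator emulates the observable data streams of a 12-week pilot
with known ground truth. Defaults (all in `CohortConfig`):

| parameter | default | rationale |
| --- | --- | --- |
| sessions/day | 3 → 0.5, linear decline | engagement is front-loaded; thinned daily Poisson is the simplest process with higher first-week and lower last-week intensity |
| active duration | lognormal, median 3 min, σ = 0.82 | reproduces a brief-usage profile with ~70% of sessions ≤ 5 min and a heavy tail |
| burst_prob | 0.3 | fraction of sessions emitted as 2–3 raw events with 2–15-min internal breaks; unconstrained by published values, chosen so burst merging is exercised without dominating the log |
| rho_freq_improve | −0.6 | planted corr(log mean gap, % improvement) |
| rho_home_severity | +0.5 | planted corr(% time at home, concurrent severity) |
| log_gap_sd | 0.7 | between-participant SD of the latent log gap, matching the spread of log-frequency values |
| GPS | 15-min cadence, 60% of days missing | whole days deleted Bernoulli(0.6) |
| home_use_schedule | 70% / 57% / 17% at home | per-phase probability a session is placed at home |
| baseline BDD-YBOCS | N(30, 4), truncated > 20, integer | eligibility requires more than moderate severity |
| improvement | N(45.3, 14.7) percent | posttreatment response distribution |

Mechanics: per participant, improvement and a frequency latent are
drawn jointly bivariate-normal at `rho_freq_improve`; the latent scales
the daily session intensity multiplicatively, so the *measured* log
mean gap is approximately linear in the latent with high reliability
(~190 gaps per participant), and the planted correlation survives the
pipeline nearly unattenuated. Severity declines linearly from baseline
to `baseline·(1 − improvement/100)`, is read off at days 0/42/84 with
±1-point uniform noise, and is clamped to the integer 0–48 scale.

Mobility: home is occupied every night (22:00–07:00); each day has one
daytime away excursion at one of `n_away_locations` (≥ 1 km apart)
whose length realizes a target percent time at home. The target is
`pct_mean + β·(severity − mean) + ε` with β and σ_ε calibrated so that
corr(target, recorded severity) equals `rho_home_severity` and the
marginal SD equals `pct_home_sd`. Calibration uses the cohort's own
pooled recorded-severity SD (computed before any mobility randomness is
drawn): the planted correlation is then exact in expectation against
precisely the values the pipeline later correlates. Days inside an
assessment window share one target (so within-window averaging adds no
noise); other days use interpolated severity with fresh daily noise.
Consequence: per-participant random *streams* are independent
(`SeedSequence` spawn keys — adding participants never perturbs earlier
streams), but the coupling slope is a cohort-level constant, so growing
the cohort shifts earlier participants' mobility *targets* slightly.

App sessions are placed inside the day's home or away block per the
phase schedule; rare collisions push a session after its predecessor.
Excursions shorter than 30 min are dropped (they could not register as
a labeled place), which caps the target percent at ~98 with negligible
attenuation.

What the generator does **not** emulate: within-day autocorrelation of
usage, multi-stop trips and realistic street-network mobility,
fix-level (as opposed to day-level) GPS dropout, location-dependent
missingness, clock drift or timezone travel, and any treatment-content
effects. Passing the recovery benchmark therefore shows the *pipeline*
is unbiased under the assumed data-generating process, not that the
markers are valid in real cohorts.

## Verification at scale

Simulation sizes were chosen to bound Monte-Carlo error while keeping
the default test run fast: planted-effect recovery and null calibration
use 50 replicate cohorts of n = 100 (mean estimates land within ±0.1 of
−0.6 and +0.5; null cohorts give mean |r| < 0.15), and home inference
is checked on 50 seeded 14-day single-participant traces (50/50
recovered). The full suite runs in roughly three minutes on one CPU.

## Known limitations

* Stay detection anchors each run on its first fix; a slow drift can
  split what a centroid-based clusterer would join. The all-pairs
  oracle in the tests bounds the disagreement on well-separated places.
* The time-at-home denominator excludes unlabeled time; cohorts whose
  members spend most time in sub-30-min stops would be poorly
  characterized.
* The night-window home heuristic fails for night-shift workers and
  multi-home participants; `n_night_observations` is reported so
  downstream users can gate on evidence.
* With 10-participant cohorts the severity/home-time estimate is noisy
  and windows lost to GPS missingness reduce n further; interpret
  single-cohort runs as demonstrations, not estimates.
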