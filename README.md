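# passivecbt

Analysis tooling for **passive smartphone data from smartphone-delivered
CBT trials** — built around the kind of 12-week open pilot in which
participants with body dysmorphic disorder (BDD) receive app-based
cognitive behavioral therapy while the app passively logs (a) every
on-app usage interval and (b) GPS fixes, and clinicians rate symptom
severity (BDD-YBOCS, 0–48) at baseline, midpoint and posttreatment.

The package answers three questions a digital-phenotyping analyst asks
of such data:

1. **How do people engage?** Raw usage events are merged into
   *sessions*: consecutive usages separated by breaks < 60 min are
   summed (two 10-min usages with a 5-min break → one 20-min session),
   and sessions with more than 60 active minutes are removed as
   outliers. From the sessions come quantity of use (total active
   minutes), frequency of use (mean end-to-start gap between
   consecutive sessions, analyzed as ln mean gap), days used, a
   duration histogram, and per-day usage series.
2. **Where are people?** GPS fixes are clustered into dwell intervals
   (≥ 30 min within 100 m), anonymized to opaque random location IDs,
   the home is inferred as the ID with the most overlap with the
   nightly 03:00–06:00 window, and percent time at home is computed in
   ±3-day windows around each clinical assessment — a candidate passive
   marker of avoidance.
3. **Do the markers track outcome?** Percent improvement
   `100·(baseline − post)/baseline` is correlated (Pearson) with
   quantity and log frequency of use, a two-predictor OLS contrasts
   them, pooled severity/home-time pairs are correlated, and a
   6000-iteration single-timepoint resampling check guards the pooled
   correlation against inflation from repeated measures.

Because raw trial data of this kind is not publicly deposited, the
package includes a first-class **synthetic cohort generator** that
emulates the data-generating process — bursty short sessions with
declining intensity, home-anchored mobility with 15-min sampling and
~60% missing days, and *planted* correlations (default −0.6 between log
mean gap and improvement, +0.5 between time at home and concurrent
severity) — so every pipeline stage is testable end to end and
parameter recovery can be verified.

## Worked example

```bash
printf 'n_participants: 10\nseed: 42\n' > cohort.yml
passivecbt generate --config cohort.yml --out cohort
passivecbt run --in cohort --out results --seed 42
passivecbt report --in results
```

prints

```
participants: 10
quantity vs improvement:      r=+0.576 (p=0.081, n=10)
log frequency vs improvement: r=-0.689 (p=0.027, n=10)
severity vs % time at home:   r=+0.222 (p=0.286, n=25)
resampled median r: +0.202 (6000 iterations)
```

Reading the output: in this seeded 10-participant synthetic cohort the
log-frequency marker tracks treatment response (r = −0.689 — shorter
breaks between sessions go with greater improvement; the planted value
is −0.6, and a single n=10 cohort scatters widely around it), while the
severity/home-time correlation (planted +0.5) is attenuated here by
GPS missingness leaving only 25 usable severity/home-time pairs. The
resampled median r (+0.202) sitting close to the pooled r (+0.222)
shows the pooled estimate is not an artifact of each participant
contributing three time points. `results/` also contains `table1.csv`
(means/SDs of improvement, quantity and log frequency with their
correlations), `daily_usage.csv` (participant × day minutes),
`severity_home_pairs.csv`, `engagement.csv`, anonymized `stays.csv`,
and the full `report.json` with exclusion logs.

At realistic scale the planted effects are recovered tightly: averaged
over 50 replicate cohorts of n=100, the pipeline estimates the planted
−0.6 and +0.5 to within ±0.1 (see `tests/test_acceptance.py`).

## Library use

```python
from passivecbt import (CohortConfig, generate_cohort, sessionize,
                        TreatmentWindow, frequency_of_use)

cohort = generate_cohort(CohortConfig(n_participants=10, seed=7))
sessions = sessionize(cohort.usage_events[cohort.usage_events.participant_id == "P001"])
mean_gap, log_gap = frequency_of_use(sessions, TreatmentWindow.full(),
                                     cohort.config.treatment_start)
```

## Layout

| module | contents |
| --- | --- |
| `passivecbt.usage_log` | usage-log I/O, burst merging, outlier filtering |
| `passivecbt.engagement` | treatment windows, quantity/frequency/days-used, histogram, daily series |
| `passivecbt.mobility` | stay detection, anonymization, home inference, % time at home, GPS missingness |
| `passivecbt.outcomes` | percent improvement, normality screen, correlation, OLS, resampling check |
| `passivecbt.synthetic` | cohort generator with planted effects and ground-truth sidecar |
| `passivecbt.pipeline` / `passivecbt.cli` | end-to-end runs, report bundle, `passivecbt` command |

Methodological details — model assumptions, parameter defaults and
their rationale, numerical choices, and what the synthetic benchmark
does and does not demonstrate — are documented in
[`docs/methods.md`](docs/methods.md).
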