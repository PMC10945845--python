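# vigilread

Time-on-task analysis of double-read breast-screening streams: does reader
performance decay over a long uninterrupted reading session (a "vigilance
decrement"), or do readers merely shift their decision threshold?

`vigilread` is a library for analysts of screening-programme reading logs.
From a time-stamped stream of recall decisions it

* reconstructs **reading sessions** under configurable break definitions
  (a break = ≥ 10/20/60/180/480 min without a decision) and derives
  position-in-session — the proxy for time on task — and per-case reading
  time;
* computes **performance curves and test accuracy** by position: recall
  rate, cancer detection rate, sensitivity/specificity/PPV/NPV with Wilson
  intervals, and the signal-detection statistics
  d′ = z(H) − z(F) and c = −½[z(H) + z(F)] with Gourevitch–Galanter
  confidence intervals, per position bin (2–30, 31–60, 61–90, 91–200);
* fits the three **multilevel models** — recall (logistic), cancer
  detection (logistic) and reading time (gamma, log link) — with a
  degree-1 B-spline in position (knots 20, 40), woman-level covariates
  (age, first screen) and nested reader-within-centre random intercepts,
  by a from-scratch Laplace approximation cross-checked against lme4;
* runs the **confound-robustness checks**: forward/reverse order
  comparison in the intervention arm, minimum-session-length
  stratification, break-length-band analysis and moved-case sensitivity;
* ships a **synthetic cohort simulator** built on the multiple-decision
  model of visual search: constant d′, a criterion drifting upward per
  case examined, partial criterion reset after breaks (full only after
  > 8 h), and gamma reading times whose log-mean declines with time on
  task.

Raw programme data are not redistributable, so the simulator is the
first-class test bed: it reproduces the programme's margins (0.82%
screen-detected cancers, 21% first screens, mean age 59, ~74 s mean
reading time at session start declining to ~55 s, median session ~35
women).

## Worked example

```python
from vigilread import (BreakDefinition, SimConfig, simulate_cohort,
                       sdt_by_bin, fit_detection_model)
from vigilread.io import attach_women
from vigilread.sessions import apply_exclusions, included, segment_sessions

women, events = simulate_cohort(SimConfig(n_women=200_000, seed=42))
first = events[events.reader_role == "first"]
merged = attach_women(first, women).sort_values(
    ["reader_id", "decision_timestamp"], kind="mergesort").reset_index(drop=True)
records = included(apply_exclusions(segment_sessions(merged, BreakDefinition(20.0))))
records = records[records.position <= 200]
print(sdt_by_bin(records).pivot(index="position_bin", columns="metric", values="value"))
```

prints (seed 42):

```
bin   d-prime   criterion
  1     2.360       0.616
  2     2.325       0.668
  3     2.350       0.678
  4     2.240       0.744
```

d′ is flat across position bins while the criterion climbs from 0.62 to
0.74: readers become more conservative with time on task — fewer false
alarms — with no loss of discriminability.  That is a threshold shift, not
a vigilance decrement.  (Pooling heterogeneous readers attenuates the
pooled d′ below the generating per-reader value of 2.79.)

Fitting the detection model on the same records
(`fit_detection_model(records).glmm.extra["or_per_5_cases"]`) gives an
odds ratio per 5 extra cases since the last break of ≈ 1.00: cancer
detection does not change over 200 consecutive cases.

Each script in `examples/` demonstrates one capability end to end
(simulation, sessionization and curves, binned SDT, model fits, robustness
checks, programme-scale projection) and prints a short interpretation.
The full pipeline — simulate → sessionize per break definition → metrics →
models → robustness, with a seed-stamped manifest — is
`vigilread.run_pipeline(PipelineConfig(...))`.

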