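# Methods

## The scientific question and the analysis pipeline

Screening readers examine long back-to-back batches of mammograms.  The
vigilance-decrement hypothesis predicts that detection performance decays
with continuous time on task; the alternative, drawn from the
multiple-decision model (MDM) of visual search, is that discriminability
(d′) stays constant while the decision criterion drifts upward — readers
become more conservative and faster, so false alarms fall with no change
in detection.  The pipeline distinguishes these by reconstructing sessions
from decision timestamps, tracking performance as a function of
position-in-session, and summarising it both as raw rates and as
signal-detection statistics.

## Sessionization

A reader's stream is cut wherever the idle gap between consecutive
decisions reaches the break threshold.  Conventions:

* a gap of exactly the threshold **is** a break (the threshold is a
  minimum idle time);
* per-case reading time is the gap to the previous decision within the
  session; it is undefined (missing) at position 1, which is excluded from
  every analysis anyway;
* duplicate timestamps within a reader are rejected, naming the reader —
  the timestamp is the only ordering key, so silent tie-breaking would
  fabricate an order;
* session ids are deterministic (`<reader>-<k>`) for reproducible joins.

Because a larger threshold ignores some breaks, sessions under threshold
T2 > T1 are exact concatenations of T1-sessions; the test suite checks
this nesting and full agreement with a brute-force segmentation on random
streams.

Analysis exclusions: position 1 (systematically different under any
session definition), positions > 200 (influential outliers), cases not
read in the intended order ("moved"), and second-reader decisions (only
the first read is blind to the other reader).  The reading-time model
additionally drops times > 600 s or recorded as 0.  Excluded records are
flagged with reasons, never silently dropped, so audit counts reconcile.

## Accuracy and signal detection

Outcomes are classified against a 3-year reference standard: recall +
cancer (screen-detected or interval) = TP, recall + no cancer = FP, etc.
Sensitivity, specificity, PPV, NPV carry Wilson score intervals.  d′ and
criterion use the equal-variance Gaussian closed forms with hit rate H =
sensitivity and false-alarm rate F = 1 − specificity; observed rates of 0
or 1 are corrected to 1/(2N) and 1 − 1/(2N) (standard SDT practice; the
correction is applied automatically in `sdt_summary` and surfaced as an
explicit error in the raw closed forms).  The d′ variance uses the
Gourevitch–Galanter binomial propagation
var(d′) = H(1−H)/(n_S φ(z_H)²) + F(1−F)/(n_N φ(z_F)²); the criterion, a
half-sum of the same two quantiles, gets a quarter of that variance by the
delta method.  All intervals are 95%.

Binned estimates (positions 2–30, 31–60, 61–90, 91–200) pool readings
across readers and break structures; pooling heterogeneous criteria
attenuates the pooled d′ below the per-reader value (visible in the
examples: pooled ≈ 2.3 vs generating 2.79).  The attenuation is common to
all bins, so the bin-to-bin *pattern* — flat d′, rising criterion — is
preserved, which is what the signature tests check.

## Multilevel models

Three models, each with the mammogram as level 1, reader as level 2 and
centre as level 3 (nested random intercepts):

| outcome          | family          | position term            |
|------------------|-----------------|--------------------------|
| recall           | binomial, logit | degree-1 B-spline, knots 20/40 |
| cancer detected  | binomial, logit | linear                   |
| reading time     | gamma, log link | degree-1 B-spline, knots 20/40 |

Covariates: woman's age (linear, centred at 59) and a first-screen
indicator.  The gamma model uses a log link — standard for positive,
right-skewed durations, and it makes the spline multiplicative.  The
detection model reports exp(5·β_position), the odds ratio per 5 extra
cases since the last break.

Estimation is a Laplace approximation to the marginal likelihood: for
candidate variance components, penalized IRLS (Fisher scoring with step
halving) finds the joint mode of the fixed and random effects; the Laplace
log-likelihood is the penalized log-likelihood at the mode minus half the
log-determinant of the random-effects information block; the two
log-SDs are then optimized by Nelder–Mead (xatol 0.02 — variance
components need far less precision than fixed effects, whose estimates are
insensitive at this tolerance), warm-starting the mode between
evaluations.  The gamma shape is profiled by the Pearson estimator at each
mode.  Fixed-effect covariance is the fixed-effect block of the inverse
joint information matrix (Wald, conditional on the estimated variance
components — the same convention as lme4's `vcov`).  A fit that stops on
the iteration cap is flagged `converged=False` and `predict_curve`
refuses it.

Fitted curves are conditional on random effects = 0 at reference
covariates (age 59, subsequent screen), with delta-method bands computed
on the linear predictor and transformed to the response scale so they
respect the outcome's range.  Degenerate groups (a reader with one record)
are retained; the penalty handles them naturally.

Cross-checks: with variance components pinned to zero the fit reproduces
statsmodels' pooled GLM to ~1e-13; with free components it agrees with R's
`glmer` (lme4, nAGQ = 1) to < 0.02 on fixed effects and SEs on a
60,000-record fixture.

## The synthetic cohort generator

The generator is the package's test bed, emulating an English-programme
reading stream.  Woman level: screen-detectable cancer prevalence 0.99%
(so that, at the operating hit rate ≈ 0.84, ~0.82% of women have cancer
*detected*, the programme's figure), interval cancers 0.20%, 21% first
screens skewed toward younger women, age truncated-normal on 47–73 with
mean 59.  Interval cancers draw their evidence from the noise
distribution — undetectable at screen, the simplest mechanism consistent
with a 3-year reference standard.

Reading behaviour follows the MDM:

* per-reader d′ fixed at 2.79 (sensitivity 0.85 / specificity 0.96
  operating point); recall decisions are Bernoulli with
  H = Φ(d′/2 − c), F = Φ(−d′/2 − c);
* the criterion starts at 0.34 plus a reader-level deviation (SD 0.08)
  and drifts up by 0.001 per case examined; a break multiplies the
  accumulated drift by (1 − reset fraction): 0 below 20 min, 0.7 for
  20 min–8 h, 1.0 (full reset) beyond 8 h — so sessions after short
  breaks start with a higher criterion than the first session of a day;
* reading time is gamma with shape solved once per configuration so the
  median/mean ratio is 36/69; its log-mean declines from 73.7 s at the
  first case to 55.1 s by the 200th case of continuous work, accumulating
  and partially resetting exactly like the criterion (saturating at the
  200-case level), plus a +15 s mean offset for recall decisions and a
  reader-level log-time deviation (SD 0.10).  Times are floored at 0.1 s
  so cumulative timestamps stay strictly increasing at float resolution;
* structure: women are grouped into intended sessions (lognormal sizes,
  median 35), each read independently by a first and a second reader from
  the same centre; in the intervention arm (default half of sessions) the
  second reader traverses the list in reverse; ~1% of adjacent pairs are
  swapped and flagged "moved".  Gaps between a reader's consecutive
  sessions are drawn from a mixture over idle bands — 55% under 15 min
  (sessions merge under the 20-min break definition), 15% 20–60 min, 12%
  1–3 h, 8% 3–8 h, 10% overnight — so a working day contains several
  multi-session runs;
* all randomness flows from a single seed through a SeedSequence
  hierarchy with one child stream per reader, so output is bit-identical
  across runs and per-reader streams are independently reproducible.

An optional woman-level confound (`woman_position_effect`) makes
early-listed women systematically easier to recall; it exists to validate
that the forward/reverse comparison discriminates woman-level gradients
(opposite trends by direction) from reader-level drift (same trend).

What the generator does **not** emulate: images or search paths,
arbitration of discordant reads, seasonal or workload trends, reader
learning, correlated errors between the two readers of a woman (their
evidence draws are independent given cancer status), or heaping/rounding
in recorded timestamps.  Passing tests therefore show that the pipeline
recovers the behavioural structure it assumes, not that real logs satisfy
those assumptions.

A second generator (`simulate_records_glmm`) draws analysis-ready records
directly from a logistic or gamma mixed model with known coefficients and
random-intercept SDs.  It exists for parameter-recovery studies: fitting a
logit model to the MDM cohort's probit-generated decisions leaves "true
coefficients" undefined, so recovery is checked where truth is exact, and
the MDM cohort is used for the qualitative signature checks.

## Problem sizes and numerical choices

The recovery and signature studies use 20 seeded replicates of ~3×10⁵
records across 50 readers (25 centres for the recovery study, chosen to
resemble the multi-centre structure of a national programme); unit tests
use 2,000–100,000 women.  Reported checks: fixed-effect bias under 10% of
the generating value, 95% Wald coverage in ≥ 17/20 replicates, the null
detection OR-per-5 interval covering 1, a one-sided sign test (≥ 15/20)
for the criterion increase from bin 1 to bin 4, and a two-sided sign test
plus a |mean difference| < 0.15 bound for d′ flatness (per-replicate d′
differences have SD ≈ 0.12 at this scale).

Other numerics: the Wilson interval is clamped to [0, 1] against
floating-point overshoot at boundary counts; the break-band analysis
assigns a session that opens a reader's stream (no observed break) to the
longest band; empty strata are flagged, not errored; a zero denominator
in an accuracy metric yields an explicit undefined (None) rather than a
fabricated value.

## Known limitations

* Variance-component uncertainty is not propagated into fixed-effect
  intervals (Wald conditional on the estimates, as in lme4); with few
  centres the centre SD is weakly identified and may collapse to zero.
* The Laplace approximation is first-order (nAGQ = 1); for very sparse
  binary outcomes per group it can bias variance components downward.
* Binned d′/criterion estimates are attenuated by pooling heterogeneous
  criteria; cross-bin comparisons remain valid, absolute levels do not
  equal the per-reader values.
* The forward/reverse discriminator loses power when short gaps merge
  many intended lists into one observed session, because the woman-level
  gradient then sawtooths within merged sessions.
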