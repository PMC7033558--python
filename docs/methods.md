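# Methods

## The model

A *hand posture simulator* is a two-boundary drift-diffusion process that
decides whether a pictured hand posture could be produced with one
specific hand.  Evidence `x(t)` starts midway between a reject boundary
(at 0) and an accept boundary and evolves as

    dx = ±v dt + s dW,

with drift `v` signed by stimulus congruence (+v when the image shows the
simulator's own hand), diffusion coefficient `s`, and a start-point bias
`z` shifting the start toward accept for the dominant/intact hand (and
away for the nondominant one).  Each trial additionally draws a *quit
time* from a log-normal distribution; if it elapses before a boundary is
reached the simulator returns a forced reject — "I give up, it's not this
hand".

Two-handed individuals are modelled as a *race* of two simulators run in
parallel, one per hand.  The first terminal event of either simulator
decides the trial: an accept names that simulator's hand, a reject or
quit names the other hand.  Congenital one-handers carry a single
intact-hand simulator, so reject and quit both map to "missing hand".
Reaction time is the deciding event's decision time plus one shared
non-decision time `Ter`.

Default group parameters are the published ones: `v = 0.1`, `z = 0.006`,
`Ter = 0.3 s`, quit-timer mean `1.6 s` and SD `1 s`, with per-group
boundary parameter `0.17` (controls) and `0.138` (congenitals), and
`s = 0.1` (the classic scaling convention; the source text leaves the
noise coefficient unstated, so it is exposed in the configuration).

### Boundary geometry

The threshold number admits two readings: total boundary separation, or
distance from the unbiased start point to each boundary (total separation
twice the number — the symmetric ±a convention of most Matlab DDM code).
Both are implemented (`threshold_convention="full" | "half"`).  The
default is `"half"`: under the full-separation reading mean first
passages at the stated parameters take ~0.45–0.6 s, almost nothing quits
before the 1.6 s deadline, and the single-simulator architecture shows
*higher* intact-hand accuracy and slightly more "intact" responses — the
reverse of the reported behavioural pattern.  Under the half reading
first passages take ~1.2 s, a substantial fraction of trials quit, and
the model reproduces the full qualitative pattern: a congenital
intact-hand accuracy deficit, a surplus of "missing" responses, a
near-balanced control group, and faster controls than congenitals.

### Quit-timer parameterisation

The quit deadline is log-normal.  By default the configured mean and SD
are *arithmetic* moments (1.6 s and 1 s), converted to the underlying
normal's parameters by moment matching: `sigma² = ln(1 + (SD/mean)²)`,
`mu = ln(mean) − sigma²/2`.  A `quit_parameterization="log"` switch
interprets them as the log-space mean and SD instead, because the source
description ("a logarithmic distribution") is ambiguous.

### Numerical integration

Euler–Maruyama with a default step of 1 ms.  Naive endpoint crossing
detection biases absorption statistics by O(s·√dt) (about half a percent
in accept probability at 1 ms, more than three Monte-Carlo standard
errors at 10⁵ trials), so within-step crossings are detected with the
Brownian-bridge crossing probability
`exp(−2(b−x_t)(b−x_{t+dt})/(s²dt))` per boundary; this makes accept
probabilities and mean decision times agree with the closed-form Wiener
absorption formulas within Monte-Carlo error at the default step.  Plain
endpoint detection remains available (`bridge_correction=False`).  A quit
and a crossing resolving in the same step resolve in favour of the
crossing; a two-simulator tie in the same step is broken uniformly at
random (steps are short, so ties are rare, and any deterministic rule
would favour one hand).  Quit events carry their drawn quit time as the
decision time.  The closed-form validation oracle
(`absorption_oracle`) uses
`P(upper) = (1 − e^{−2vw/s²})/(1 − e^{−2va/s²})` and
`E[T] = (a·P − w)/v`, with the drift→0 limits `w/a` and `w(a−w)/s²`.

### Fitting

`fit_parameters` is an exhaustive grid search — the automated stand-in
for the original hand-tuning to group-level means.  Every grid point is
simulated with the same trial count and the same seed (common random
numbers) and scored by the equal-weight sum over hands of squared
accuracy error (proportion scale) and squared mean-correct-RT error
(seconds scale); the weights are configurable since no objective function
was specified for the original manual fit.  Groups are fitted
independently, which reproduces the published situation in which only the
boundary parameter differs between groups while the other four parameters
are shared.

## The behavioural pipeline

The analysis chain mirrors the empirical treatment of the task data:

- **Hand mapping.** Left/right stimulus sides and verbal responses map to
  intact/missing per subject: a one-hander's missing side, a control's
  nondominant side.
- **Trial filtering.** Noisy-recording and no-response trials are
  dropped; subjects at or above a 27% no-response rate (the rate at which
  a participant was excluded from the study) are flagged for exclusion
  but not silently removed.
- **RT transform and trimming.** Natural log (the base is a free choice;
  it does not affect trimming or rank statistics and is recorded here),
  correct valid trials only, then a single trimming pass removing trials
  beyond ±3 SD of the subject×condition cell mean; cells under 3 trials
  are skipped with a warning.  Trimming is not iterated because removal
  counts are expected to be tiny (≤2 per participant in the reference
  data).
- **Difficulty.** Per-image median RT over an independent reference
  group's correct trials, median split across images; ties at the median
  go to easy.  Mirrored left/right image pairs with equal reference RTs
  always share a class.
- **Signal detection.** Signal = intact-hand image.  `d′ = z(H) − z(F)`,
  `c = −(z(H)+z(F))/2`, so positive c is a bias toward reporting
  "missing".  Extreme rates are corrected by the 1/(2N) rule (0 →
  1/(2N), 1 → 1 − 1/(2N)), the most common of the standard corrections.
- **Motor and prosthesis scores.** Phantom motor control is the mean
  duration of five finger-thumb opposition cycles (total/5 when only a
  total is recorded); the prosthesis-usage compound is the sum of
  within-cohort z-scores (sample SD) of the activity-log and wear-time
  ratings.
- **Subject outliers.** Subjects beyond ±3 SD of their group mean per
  condition are flagged, not removed, supporting repeat-with/without
  analyses.

## Dependent correlations

`spearman` is the average-rank coefficient with an exact permutation
p-value for n ≤ 8 and the t approximation above that.
`dependent_corr_test` implements Steiger's Z1* with the pooled
correlation r̄ = (r_jk + r_jh)/2 in the covariance term, plus the
Hotelling–Williams t (df = n−3) as an alternative, since these are the
two standard candidates for "two dependent correlations with one variable
in common"; applied to Spearman rhos the procedure is the common-practice
approximation.  Monte-Carlo calibration under a trivariate-normal null
(equal population correlations, n = 15) keeps the empirical type-I error
within [0.03, 0.07] at α = 0.05 over 10⁴ replicates.

## The synthetic-data generator

`generate_cohort` emulates the study design: 21 controls / 16 amputees /
17 congenital one-handers, 2 blocks × 48 images (24 per side, mirrored
pairs sharing a difficulty class), a 2.8% noisy-recording rate,
per-subject no-response rates with mean 2% bounded by 10.4% (Beta(1, b)
scaled to the ceiling), and a 5 s display limit past which a trial counts
as no response.  Trial outcomes come from the model itself: controls and
amputees from the two-simulator race, congenitals from the single
simulator.  Amputees use the control architecture because the model
covers only controls and congenitals while amputees behave control-like
empirically.  On top of the model's decision times the generator applies
a hard-image inflation factor (default 1.25), a subject-level log-RT
offset (SD 0.08) and log-normal trial noise (SD 0.15 log units) — values
chosen for plausibility; the real per-condition variance components are
unknown without the raw data, and these are recorded in the ground-truth
output rather than asserted as faithful.

Amputee phantom-motor times are log-normal (log-mean 3.0 ≈ 20 s per five
cycles, log-SD 0.6, matching the published covariate range) and coupled
to each amputee's *realised* mean laterality RT through a Gaussian
copula at Pearson level `2·sin(π·ρ_s/6)`, so the target Spearman
correlation (default 0.7, the scale of the reported effect) is achieved
in expectation regardless of trial noise.  Age at amputation is uniform
over 17–45 years (the published range) constrained below current age;
prosthesis ratings are correlated uniforms on a 1–5 scale.

The generator uses a 4 ms integration step (vs the model default of
1 ms): with bridge-corrected crossing detection the discretisation bias
is far below the injected trial noise, at a quarter of the cost.

`worked_fixture` is a fully constructed 3-subject table (no randomness)
whose accuracy (10/12), exclusion flag (4/12 no-responses = 33% ≥ 27%)
and signal-detection indices (H = 5/6, F = 2/6) are hand-checkable; it
anchors byte-identical regression tests of the pipeline.

## What passing tests do and do not show

The generator reproduces the *structure* the pipeline assumes — group
sizes, stimulus schedule, validity flags, covariate coupling — not the
empirical RT distributions, inter-subject variance components, or any
image-specific difficulty ordering.  Within-cohort signal-detection
results follow from the generating model, so the synthetic congenital
group shows a higher d′ than its empirical counterpart (where
discriminability did not differ between groups); tests passing on
synthetic cohorts validate the computations, not the model's fit to raw
data.  Group-level ANCOVA-style omnibus tests and analyses of the
original dataset are out of scope.

## Problem sizes

Validation simulations use 10⁵ trials for oracle equivalence, 5 × 10⁴
trials per hand for group predictions, a 5×5 grid at 4 × 10³ trials per
hand per evaluation for parameter recovery, 10⁴ replicates for test
calibration, and 100 cohorts for generator-fidelity checks.
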