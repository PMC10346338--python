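# Methods

This note records the statistical model the package implements, the
estimators and their numerical details, what the synthetic-data generator
does and does not emulate, and the design choices made where the design was
genuinely open.

## Measurement model

A biometric sample from participant *i* in situation *j* is modelled as

```
x_ijk = mu + r_i + s_j + v_ijk
```

with independent Gaussian components: participant effects
`r_i ~ N(0, sigma_r^2)` (constitutional differences — age, fitness,
chronic state), situation effects `s_j ~ N(0, sigma_s^2)` (activity,
stress, sleep/wake state), and residual noise `v_ijk ~ N(0, sigma_v^2)`
(sensor noise plus moment-to-moment physiology). The two-component form
without `s_j` underlies between-person reliability,
`rho = sigma_r^2 / (sigma_r^2 + sigma_v^2)`. Gaussianity is a modelling
choice: the variance-components formulation itself fixes only means and
variances, and the normal distribution is the conventional completion.

## Between-person reliability (ICC)

`decompose_oneway` computes the one-way ANOVA mean squares over
per-participant replicates: `MSBS = SSB / (n-1)` with SSB the
replicate-weighted sum of squared deviations of participant means about the
grand mean, and `MSWS = SSW / sum_i(k_i - 1)`. Participants with fewer than
two replicates carry no within-participant information and are dropped with
a warning.

- **Single-measure** `ICC(1,1) = (MSBS - MSWS) / (MSBS + (k-1) MSWS)`;
  **average-measure** `ICC(1,k) = (MSBS - MSWS) / MSBS`. The two are linked
  by the Spearman–Brown relation, which the tests verify.
- **Unbalanced designs** substitute Searle's effective replicate count
  `k0 = (N - sum k_i^2 / N) / (n - 1)` for k and flag the result. The
  balanced-k formula is the textbook case; real wearable tables are almost
  never balanced, so the bridge is part of the contract rather than an
  afterthought.
- **Confidence interval**: Shrout–Fleiss one-way F bounds. With
  `F = MSBS/MSWS`, `FL = F / F_{1-a/2}(n-1, dfw)` and
  `FU = F * F_{1-a/2}(dfw, n-1)`; the ICC bounds are `(FL-1)/(FL+k-1)` and
  `(FU-1)/(FU+k-1)` (without the k-1 inflation for the average-measure
  form). Coverage is verified by simulation (95% CI covers the true rho in
  93–97% of 1000 studies at n = 50, k = 5, rho = 0.5).
- **p-value**: one-sided F test of ICC = 0 on (n-1, dfw) degrees of
  freedom.
- The sample statistic's algebraic range is `[-1/(k-1), 1]`; estimates are
  never clipped. Classification bins default to >= 0.75 excellent,
  [0.40, 0.75) good, [0.25, 0.40) fair, < 0.25 poor — the usage convention
  of the wearable-reliability literature this package serves, which differs
  from Cicchetti's bins; they are configurable.
- Degenerate inputs: all-identical data (0/0) raises an explicit
  undefined-estimate error; `MSWS = 0` with signal returns exactly 1.

## Within-person reliability (split-half)

Analysis units are cells such as participant x activity (laboratory
protocols) or participant x study-day x state (ambulatory wear); both ship
as presets. Within a unit, samples are numbered 1..m by acquisition time.

- **Time-sensitive split**: odd positions vs even positions, so paired
  samples are as close in time as possible. Numbering starts at 1 and the
  odd half receives the extra sample for odd m.
- **Random split**: a uniformly random partition into halves of sizes
  ceil(m/2) and floor(m/2). Each partition is fully determined by
  (master seed, iteration index, unit identity) through a seed sequence
  keyed by a CRC of the unit label, so iterations are independent and any
  single unit's partition is reproducible in isolation.
- **Direction convention**: the even half is the predictor and the odd half
  the criterion. The method itself is direction-agnostic; a fixed,
  documented convention keeps outputs comparable, and a sanity test bounds
  the fwd/rev slope difference by the fit's standard error.
- **Model**: `criterion ~ a + beta * predictor` with random intercepts only
  (no random slopes) for the requested factors — participant always,
  situation when units vary within participants beyond the split factor.
- **Resampling summary**: mean and SD of beta over converged iterations
  (1000 by default). Failed or non-converged fits are counted, excluded
  from the summary, and a failure rate above 10% attaches a prominent
  warning rather than silently degrading the estimate.

## Mixed-model engine

The models above are small random-intercept LMMs, fitted by profiled REML:
with `V = sigma2 (I + sum_g gamma_g Z_g Z_g')`, both the fixed effects and
sigma2 profile out, leaving an optimisation over log gamma (bounded Brent
for one factor, Nelder–Mead with three starts for crossed factors).
Satterthwaite degrees of freedom for each fixed-effect t statistic use the
closed-form expected REML information `0.5 tr(P dV_i P dV_j)` and the exact
gradient of the coefficient variance — no numerical differentiation. The
engine is cross-checked in the tests against statsmodels MixedLM
(estimates, standard errors, variance components) and R's lmerTest (beta,
SE, Satterthwaite df, p); lmerTest differentiates the observed REML
criterion numerically, so df agree to ~1% rather than machine precision.
This engine exists because no installed Python library exposes Satterthwaite
degrees of freedom for LMMs; it is not a reimplementation of an available
routine.

Numerical choices: variance ratios are floored at 1e-10; a perfect linear
fit (SSE below 1e-12 of the response scale) short-circuits to OLS with
residual degrees of freedom n - p, which keeps noiseless benchmarks exact
and avoids a degenerate REML surface; rank-deficient or constant-predictor
designs raise explicit errors; Satterthwaite df are floored at 1 and fall
back to n - p if the information form is numerically singular.

## Preprocessing and segmentation

Cleaning is two-pass and order-fixed: zero-valued samples first (the vendor
emits 0 for failed reads, especially HRV), then values more than `n_sd = 2`
sample standard deviations (divisor n-1, strict inequality) from the
participant's mean, computed once per participant-metric over the whole
observation period — not per day or condition. The outlier filter is
deliberately applied once, never iterated to a fixed point. Per-metric
removal counts and fractions accumulate in the stream's filter log.
Series under 3 samples skip the outlier filter (SD unstable).

Sleep detection: per participant, maximal runs of BPM samples with
inter-sample gaps <= 15 min; runs spanning >= 2 h qualify; the longest
qualifying run per study day is the sleep period (earliest wins ties).
Study days run noon-to-noon in local time so a night crossing midnight
belongs to one day; timestamps must therefore carry explicit UTC offsets,
and naive timestamps are rejected at ingestion. Interval membership is
closed on both ends. Exclusions: participants with fewer than 3 detected
sleep periods are dropped (the weakest rule consistent with excluding 1–2
period participants while keeping >= 5); participant-days with fewer than
2 wakeful rMSSD samples lose those records. Both thresholds are
configurable, and every exclusion is itemised in a report.

## EMA scoring and lagged models

Prompt scores: negative affect is the mean of (irritable, afraid, nervous,
angry), positive affect the mean of (happy, energetic); pain and discomfort
ride along in the data model but are never scored. A scale is scored when
at least half its items are present — a package choice, since partial
prompts have no canonical rule. Daily scores average prompts within the
local calendar day.

Daily biometrics are keyed so that a night is addressed by the morning it
ends on: wake records by calendar day, sleep records by study day + 1.
The six models — {BPM, rMSSD} x {concurrent wake, preceding night,
following night} — regress the biometric on the two affect scores with a
participant random intercept (biometric as outcome, affect as predictor:
the convention of the design this mirrors, even though the interesting
reading runs the other way). Bonferroni uses one family of m = 6; raw and
corrected p-values are both reported, and the headline coefficient is the
negative-affect one, with the positive-affect stats carried alongside.

## Synthetic data

The stream generator reproduces the statistical regime the estimators
assume: a 5-minute sampling grid; every grid point emitted inside a nightly
23:00–07:00 sleep window; wakeful points retained independently with
probability 0.10 (matching roughly 19 successful wakeful BPM samples per
day against ~97 sleep samples); each (day, state) cell carrying its own
situation effect; residual SD differing between sleep and wake. Study
presets: BPM mu 70, sigma_r 8, sigma_s 3, sigma_v 2 (sleep) / 6 (wake);
rMSSD mu 50, sigma_r 15, sigma_s 5, sigma_v 8 (sleep) / 25 (wake), zero
rate 0.1926, outlier rate 0.02. The rMSSD wake SD of 25 keeps physically
impossible negative draws under ~5%; such draws are clipped to zero at the
artifact stage, where a failed read is exactly what a negative value would
mean.

Artifacts are injected *after* the noise-free truth is stored, so filters
can be scored for exact recall: negative clipping, Bernoulli zero
replacement (rMSSD), and deterministic spikes at participant mean + 4 SD —
deterministic rather than heavy-tailed so the 2-SD filter's expected
behaviour is analysable. EMA prompts are drawn 6/day at random times in
08:00–20:00 with integer 1–10 items; an optional planted association
shifts next-day negative-item means linearly with the preceding night's
true sleep-mean biometric before rounding and clipping.

What the generator does **not** emulate: circadian heart-rate curves,
respiratory sinus arrhythmia, autocorrelated within-unit noise, motion
artifacts correlated with activity, or device clock drift. Passing tests
therefore certify the estimators and pipeline plumbing under the assumed
variance structure, not robustness to physiological serial dependence —
on real streams, time-sensitive and random splits can legitimately diverge
(and did, in the data this framework was built for).

## Problem sizes

The test suite and acceptance script scale their simulations to what the
statistics require rather than to realism: ICC recovery at n = 500
participants x 8 replicates; CI calibration over 1000 simulated studies at
n = 50, k = 5; split-half checks on 5–7 day streams of 6–10 participants
with 200–1000 random splits; EMA null calibration over 200 replicates of an
8-participant, 6-day study. The null-calibration check compares the
rejection rate to its own replicate-level Monte-Carlo standard error rather
than a fixed band, which keeps it honest at any replicate count.

## Known limitations

- One-way ICC only; systematic device effects (a two-way design) are out of
  scope, as is raw PPG beat detection.
- The sleep detector equates dense sampling with sleep; still wakefulness
  (reading, movies) is indistinguishable and biases wake samples toward
  sleep-like reliability.
- Satterthwaite df use expected rather than observed information; with very
  few groups both are approximations, and the two can differ by a few
  percent.
- The resampling distribution of betas is summarised by mean/SD/quantiles;
  no step-up (Spearman–Brown) correction is applied to split-half slopes.
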