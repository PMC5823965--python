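# Methods

## Task model

Each session comprises 8 blocks × 50 trials.  Every trial shows a left or
right arrow (go stimulus) after an 800-ms fixation; on a random 25% of
trials a sound (the stop signal) follows the arrow at the current
stop-signal delay (SSD).  Outcomes follow the independent horse-race
model: the go process finishes at `T_go`, the stop process at
`SSD + T_stop`, and a response escapes iff `T_go < SSD + T_stop`.  Ties
are resolved in favor of stopping; under continuous latencies they have
probability zero, so the choice is inconsequential but fixed.

`T_go` is ex-Gaussian (defaults μ=330, σ=40, τ=45 ms, giving a mean go RT
of 375 ms).  `T_stop` is normal per condition, truncated at 1 ms
(defaults: 203 ms emotional, 217 ms neutral, SD 30 ms), encoding the
emotional facilitation of stopping as a 14-ms latency advantage.  Go
omissions (default probability 0) and choice errors (default .016) are
applied independently; a response later than the deadline (trial end,
1200 ms after go onset) counts as an omission, and a go omission on a
stop trial counts as a successful stop, since no response occurred.

One staircase is shared by both conditions: SSD +50 ms after a successful
stop, −50 ms after a failed one, clamped to 100–400 ms (seven lattice
values), starting at 150 ms.  This 1-up/1-down rule converges on the SSD
where the inhibition probability crosses 50%.  In 200 simulated default
sessions the mean inhibition rate is ≈48.6%: the tracking is slightly
below the nominal 50% because the staircase starts low (150 ms), spends
its early trials below the equilibrium point, and the inhibition-vs-SSD
function is not antisymmetric around its crossing on the discrete 50-ms
lattice.

### Stop-schedule balancing

With 100 stop trials and 99 consecutive-category transitions, the four
ordered condition pairs (EE, EN, NE, NN) cannot all occur equally often;
counts are a permutation of {25, 25, 25, 24}.  The sequence is drawn as a
uniformly seeded Eulerian trail on the two-node transition multigraph
(Hierholzer's algorithm with shuffled edge order), which realizes exactly
those counts while keeping 50 trials per condition.  Each condition's
five sounds are assigned five left- and five right-arrow occurrences,
shuffled; when a non-default configuration makes exact balance impossible
the assignment is as even as integer arithmetic permits.

## SSRT estimation

The integration method: go RTs from all no-stop-signal trials with a
response (choice errors included by default; a flag restricts to correct
responses) are pooled and rank-ordered; the n-th RT with
`n = ceil(p_respond × N)` clamped to [1, N] is selected; SSRT is that RT
minus the mean SSD.  The ceiling is a documented convention — the
selection rule is stated in the literature only as "multiply N by the
probability of responding".  Scopes:

- *global*: p_respond over all stop trials; mean over all realized SSDs,
  including the initial 150 ms.
- *emotional/neutral*: condition-wise p_respond; the SSD average uses the
  SSDs realized on the stop trial directly **following** each
  emotional/neutral stop trial (those SSDs are the staircase's response
  to that condition's outcomes).  The session's final stop trial has no
  follower and contributes none; the initial SSD belongs only to the
  global mean.

With a fixed SSD `s` and a constant stop latency `T`,
`P(respond) = P(T_go < s + T)`, so the p-quantile of the go distribution
is `s + T` and the estimate converges to `T`; the test suite verifies
|bias| < 5 ms at ~10,000 go trials, and recovery of a 15-ms condition
difference within ±5 ms over a 32-subject cohort.  Under the full
staircase the follower-SSD rule induces a small positive bias in the
condition difference (≈2–4 ms at default settings), a known property of
staircase-based condition-wise estimation.

## Synthetic EEG

32 channels (extended 10–20 montage), 256 Hz.  Each component is a
Gaussian bump in time (peak latency, FWHM) times a signed amplitude times
a fixed topographic map (weight 1.0 over the component's analysis
cluster, 0.3 elsewhere).  Planted content per trial:

| component | lock | peak (ms) | FWHM (ms) | planted on |
|---|---|---|---|---|
| go-evoked | go onset | 300 | 250 | every trial |
| N1 | stop onset | 155 | 60 | stop trials |
| P3 | stop onset | 337.4 EMO / 368.7 NEU | 120 | stop trials |
| ERN | response | 40 | 50 | failed-stop responses |
| Pe | response | 190.5 EMO / 217.9 NEU | 140 | failed-stop responses |

Cell mean amplitudes follow the study's ordinal pattern (aversive >
neutral for N1, P3, Pe; ERN near-equal; successful > failed stops for N1
and P3).  The go-evoked wave is deliberately slow and late — the go
stimulus elicits its own late positive complex — because its tail
reaching the P3 scoring window through SSD-dependent temporal offsets is
exactly the differential-overlap problem the equal-weight subaveraging
corrects.

Correct-response epochs contain no ERN/Pe by construction and successful
stops produce no response marker.  The small nonzero HIT-cell values the
scoring reports arise purely from go-evoked overlap relative to the
pre-response baseline.

Background noise is a 1/f + white mixture (defaults 6 and 3 µV SD).  With
per-trial probability .06 a broadband burst (SD 150 µV) is added to one
channel across the trial, so that roughly 6% of epochs exceed the ±65 µV
rejection bound — matching the reported rejection rate.  A DC offset
would be removed by baseline correction, which is why the artifact is a
burst.

### Cross-subject structure

Per subject, each component family gets one standardized level score
(z_N1, z_P3, z_Pe, z_ERN) scaled by a between-subject SD, with
`z_Pe = .82 z_P3 − .22 z_N1 + ε`, corr(z_P3, z_N1) = .16 and
SD(ε) = sqrt(1 − .663) — the unique scaling under which the population
standardized betas, predictor correlation and R² simultaneously equal
.82/−.22, .16 and ≈.66.  An analogous emotional-enhancement layer
generates per-subject EMO−NEU difference scores with
`z_dPe = .60 z_dP3 − .22 z_dN1 + ε₂`, corr .33, population R² ≈ .32, so
the difference-measure regression also has real structure; the ERN
difference score is unlinked noise (the ERN condition effect is null at
the population level).  The subject's failed-stop P3 latency is coupled
to the subject's stop-latency deviation (0.5 ms/ms plus residual), giving
slower stoppers later P3 peaks; Pe latency varies independently.

## ERP analysis

Time-to-sample mapping: an epoch from t0 to t1 ms starts at sample
`round(t0·fs/1000)` relative to the lock event (lock = sample 0) and
spans `round((t1−t0)·fs/1000)` samples — the −100..700 ms stop-locked
window at 256 Hz is exactly 205 samples.  Analysis windows *inside* an
epoch map both endpoints with `round()` and are inclusive on both; window
edge inclusiveness is a package convention, as the original endpoints are
stated only in milliseconds.  Baselines: −100..0 ms (stop-locked),
−150..−50 ms (response-locked), subtracted per channel.

Rejection removes any epoch with a sample strictly beyond ±65 µV; it is
idempotent and conserves counts.  Condition averages for stop-locked data
first average within each SSD bin holding at least `min_per_bin` epochs
(default 1 — no minimum is prescribed, bins per subject are few) and then
average the bin means with equal weight.  Because the go-evoked overlap
inside a stop-locked epoch depends only on the SSD, two conditions with
different SSD histograms but identical stop-locked components then have
identical expected overlap; on the standard test fixture the equal-weight
collapse reduces the spurious P3-window condition difference by well over
5× relative to naive pooling.  Response-locked cells use plain averaging:
the subaveraging procedure applies to stop-signal ERPs, and HIT trials
carry no SSD.

Mean amplitude is the mean over the cluster channels and window samples.
Peak latency is the polarity-appropriate extremum of the cluster-mean
waveform within the window, plateau ties resolved to the earliest sample.

## Statistics

- Paired *t*: two-tailed; both d_av (|Δ|/mean of the condition SDs) and
  d_z (|t|/√n) are reported because the source summary statistics are
  consistent with different d conventions in different places; outputs
  label the variant.
- 2×2 repeated-measures ANOVA: full within-subject SS decomposition, each
  1-df effect tested against its effect-by-subject interaction; partial
  η² = SS_eff/(SS_eff+SS_err) = F·df1/(F·df1+df2).  Two-level one-way
  repeated factors are reported as F = t² of the paired contrast.
- Standardized regression: OLS on z-scored variables via statsmodels;
  model F(k, n−k−1); collinearity is rejected naming the offending
  predictors.
- Steiger's Z for two dependent correlations sharing one variable:
  Fisher-z difference scaled by the asymptotic covariance; the default
  "updated" variant plugs the average of the two compared correlations
  into the covariance (the pooled refinement), `classic` uses the
  individual correlations.  Under a trivariate-normal null at n=32 the
  empirical size is ≈5% (verified over 10,000 replicates).
- Power of the paired *t*: noncentral *t* with ncp = d_z·√n, df = n−1;
  tails are an explicit argument (one-tailed power at n=32, d_z=0.5,
  α=.05 is ≈.87).
- Normality screening: Lilliefors-corrected KS against a normal with
  sample-estimated parameters by default; the classic known-parameter
  p value is available by flag and is anticonservative when parameters
  are estimated.  Bonferroni: min(1, p·m).

## Pipeline

`run_pipeline` derives all module seeds from one master seed (every
subject's session/ERP/EEG seed is logged), simulates the cohort,
synthesizes EEG, scores the four stop-signal cells (SUCC/UNSUCC ×
EMO/NEU, equal-weight SSD collapse), the pooled failed-stop cell, and the
three response cells (HIT, EMO error, NEU error), then runs the paired
tests, the ANOVA table, Bonferroni-corrected post-hocs, both regressions
(raw amplitudes; difference measures), the SSRT–latency correlations and
their Steiger comparison, and the normality screen.  Reruns with the same
config and seed are byte-identical; stage subcommands re-derive upstream
intermediates deterministically, so chained stages reproduce `run-all`
exactly.

Problem sizes used by the test suite: full 400-trial sessions where the
design constants are asserted; 200 sessions for staircase convergence;
~10,200 go trials for the SSRT closed-form limit; 32-subject cohorts for
parameter recovery; 200 replicate cohorts for the regression-calibration
check; 10,000 replicates for the Steiger null; shorter 80-trial sessions
wherever only mechanics are exercised.

## What the generator does and does not emulate

Passing tests show that the analysis chain recovers what was planted
under the generator's assumptions; they do not certify performance on
real recordings.  Known simplifications and emergent artifacts:

- No volume conduction, ocular/muscle artifact morphology, line noise, or
  filtering; topographies are schematic weight maps.
- Component shapes are Gaussian; real N1/P3/ERN/Pe are asymmetric and
  multi-peaked.  Single-trial amplitude/latency jitter is not modeled
  beyond additive noise.
- Amplitude calibration targets the *ordinal* cell pattern, not exact
  published cell means: overlap shifts absolute scored values (e.g. the
  HIT-cell Pe is pulled negative by the go-evoked wave relative to the
  pre-response baseline).
- Because stop-locked and response-locked windows genuinely overlap in
  time on failed-stop trials, scored response-locked condition contrasts
  inherit part of the planted stop-locked condition differences: the
  EEG-level regression R² runs higher than the latent .66 calibration,
  and the planted-null ERN condition effect can reach nominal
  significance in some cohorts.  This mirrors the real aggregation
  concern the overlap-correction literature discusses, and is why the
  generator-level parameter-recovery checks are run on the latent subject
  parameters.
- The SSRT–P3-latency correlation produced by the default coupling is
  attenuated by scoring noise (single-subject peak estimates on ~25-epoch
  averages) and is weaker than in published human data.
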