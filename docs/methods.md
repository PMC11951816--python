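# Methods

## Scope and data model

`hrval` validates 1 Hz heart-rate traces from test devices (PPG-based,
worn on upper arm, forearm or either wrist) against a criterion trace
(ECG-like chest strap). The atomic datum is an `HRSeries`: one device's
trace for one subject and session, with per-second timestamps, an
activity label (or `rest`), and bpm values where NaN means missing.
Zeros in input files are parsed as missing — commercial loggers commonly
emit blanks or zeros during signal loss.

## Synthetic cohort generator

The generator exists so the whole pipeline can be exercised against
known ground truth; it defines the study conditions the tests run under.

**Protocol.** The default protocol has nine activities in order of
increasing intensity — lying 5 min, sitting 5 min, walking 15 min,
picking up objects 8 min, jogging 8 min, weight training 8 min, cycling
8 min, HIIT 8 min, postexercise sitting 20 min — with 2-minute rests
between activities and two sessions per subject (20-minute break, not
simulated as data). One session is 6060 s of which 5100 s are activity.

**Reference dynamics.** Each activity has an `intensity` (fraction of
the subject's HR reserve); the resolved target is
`resting_hr + intensity × hr_reserve`. A first-order filter relaxes HR
toward the running target with time constant `tau_s` (default 35 s,
an ordinary on/off-kinetics scale for submaximal exercise), HIIT
alternates its target as a square wave with the protocol's 45 s effort /
15 s recovery duty cycle, and white intrinsic variation
(`intrinsic_sd`, default 1.5 bpm) is added on top before clipping to
the physiological 30–230 bpm range. The white noise is added after the
filter rather than inside the recursion so `intrinsic_sd` is the actual
marginal SD of the output; injected into an AR(1) recursion it would be
inflated by ≈ √(τ/2). The `intensity` encoding (not absolute bpm) is
what makes one protocol reusable across subjects with different resting
HR and reserve while keeping every resolved target inside [30, 230].

**Population defaults** (all configurable): resting HR ~ Normal(60, 8)
truncated to [40, 90] bpm; HR reserve ~ Normal(120, 15) clipped so
resting + reserve ≤ 230; τ ~ Normal(35, 5) floored at 5 s. Child seeds
derive deterministically from (cohort seed, subject index, position
index), so any subject subset reproduces bit-identically.

**Device error model.** A device trace is the reference shifted by an
integer clock lag (samples whose source precedes the recording start are
missing), plus a constant bias, plus Gaussian noise with per-sample SD
`noise_sd + motion_gain × motion_level(activity)`, with samples
independently dropped (missing) at `dropout_rate` and displaced by
single-sample spikes of ±`spike_magnitude` (default 40 bpm, chosen to
clear the 15 bpm jump threshold unambiguously) at `spike_rate`.
An optional session-2-only bias exists to probe the reproducibility
test. Single-sample spikes are deliberate: the type III rule labels both
the jump and the return edge, which the filter-correctness tests pin
down exactly.

**What the generator does not emulate:** raw PPG/ECG waveforms,
RR-interval variability, HR drift within steady state, skin-tone or
temperature effects, clock drift beyond a constant offset, or
non-stationary artifact bursts. Passing tests therefore demonstrate
correctness of the pipeline's bookkeeping, estimators and calibration
under a controlled error model — not field accuracy of any real device.

## Cleaning chain

Order is fixed: rest removal → synchronization → artifact/missing
handling → flagging and reference screening → window averaging.

- **Synchronization.** The lag is the integer L ∈ [−120, 120] maximizing
  Pearson correlation between device[t] and reference[t−L] over
  pairwise-complete samples (no imputation anywhere); ties break toward
  the smallest |L|, then the negative one. It is estimated once per
  subject × session × device, pooling activities, because a clock
  offset is a property of the recording, not of the activity. Noiseless
  shifted traces recover L exactly for every |L| ≤ 120.
- **Artifacts.** Type I: < 30 bpm. Type II: > 230 bpm. Type III:
  |Δ| ≥ 15 bpm between adjacent seconds with both samples present; the
  threshold is inclusive (a printed threshold of 15 reads naturally as
  "a jump of 15 is an artifact"), and the *later* sample of the jump is
  labeled, preserving the pre-jump sample that agrees with history.
  Range violations take precedence; jumps into or out of a type I/II
  sample are not double-counted. Missing values are counted separately
  and never as artifacts. All of this is configurable.
- **Flagging.** A subject × session × activity × position segment is
  flagged when either side has > 10 missing samples, either side has
  > 10 artifacts, or device–reference correlation over retained pairs is
  < 0.9 (segments with < 3 retained pairs, or a constant side, count as
  low-correlation). Thresholds are strict ("more than 10"), so exactly
  10 does not flag.
- **Reference screening.** Visual screening of the criterion is replaced
  by a deterministic rule — reproducibility requires an explicit
  criterion. A flagged activity is excluded (for all positions of that
  subject-session) only when the reference itself is implicated: its own
  artifact count exceeds the flag threshold, or the activity is
  low-correlated against ≥ 2 independent device positions. A single
  noisy device never removes an activity.
- **Windowing.** Non-overlapping 10 s windows anchored at each
  activity's start (half-open [t₀+10k, t₀+10(k+1))). Window means are
  computed over retained pairs (both sides present) for device and
  reference separately; windows with fewer than 5 retained pairs
  (half a window — no published minimum exists, so the default is the
  natural midpoint) and trailing partial windows are dropped.

## Agreement statistics

Computed per activity × position and overall per position, pooling
windows across subjects — the layout of a conventional validation
table. Pooling ignores within-subject correlation of windows, so the
one-sample *t* test is anti-conservative under pseudo-replication; a
per-subject-then-average variant (`aggregate="subject_mean"`) is
provided for sensitivity analysis but is not the default, to keep the
table comparable with the literature.

- LoA use the fixed 1.96 multiplier (95% under normality), not the
  small-sample t quantile; configurable.
- Lin's CCC uses population (1/n) moments — the standard estimator —
  and its CI is a Fisher-z interval with Lin's asymptotic SE. Degenerate
  inputs (|CCC| = 1) collapse the CI onto the point estimate.
- 5%-accuracy is boundary-inclusive (|d|/ref ≤ 0.05).
- Groups too small or degenerate for the battery (n < 3, zero variance)
  report their n with the statistics left unavailable, never fabricated.
- Algebraic identities maintained to 1e-9 and tested: RMSE² = bias² +
  population Var(d); OLS r² = Pearson r²; |CCC| ≤ |r|.

## Reliability

**WSCV.** The within-subject coefficient of variation of the paired
differences: per subject, Var(d) over that subject's windows in the
group; pooled across subjects with df weights Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1); then
100·√(pooled)/mean reference HR of the group. A pure per-subject bias
does not move it — only within-subject error variability does; it
scales linearly in the device noise SD. A classical test-retest CV
would use repeated measurements of the same quantity; here the repeated
quantity is the device-minus-reference error, which is what "device
consistency against the criterion" means operationally, and its
magnitude tracks the spread of the limits of agreement relative to mean
HR. Interpretation bands: < 5% high, < 10% acceptable, ≥ 10% poor
reliability.

**Between-session reproducibility.** Wilcoxon signed-rank on paired
subject × activity cell mean differences (session 1 vs session 2):
cell means rather than pooled windows keep the pairs exchangeable and
the pair count at subjects × activities. Zero differences are dropped
(Wilcoxon's original method); the null is enumerated exactly for n ≤ 25
untied pairs and approximated normally with tie and continuity
correction otherwise; W is reported as min(W⁺, W⁻). An all-zero input
is vacuous and reported as W = 0, p = 1, flagged degenerate.

## Interpretation bands

MAPE: < 3% very high, < 5% high, < 10% moderate, else low accuracy.
Pearson r: 0.45–0.69 very poor, 0.70–0.84 poor, 0.85–0.94 good,
0.95–0.994 very good, > 0.995 excellent; values below 0.45 are labeled
`below_scale` rather than forced into the lowest band. CCC (McBride):
< 0.90 poor, 0.90–0.95 moderate, 0.95–0.99 substantial, > 0.99 almost
perfect. Band edges follow a lower-edge-inclusive convention so the
printed ranges tile the scale without gaps: "0.85–0.94" next to
"0.95–0.994" becomes [0.85, 0.95) and [0.95, 0.995). Classification is
total and deterministic over finite inputs; NaN maps to `unavailable`.

## Problem sizes

The test suite and the acceptance script run cohorts of 16 subjects
over the full default protocol for parameter recovery (one pipeline
pass each), 500 cohort replicates for the session-test false-positive
calibration (computed on per-activity cell means with identity
alignment, the sufficient path for that statistic's null), 40
replicates for its power check, 10⁴ replicates at n = 50 for t-test
calibration, and n = 10⁵ draws for LoA coverage — sizes at which the
binomial/CLT tolerances asserted in the tests are meaningful.

## Known limitations

- The t test's pooled-window pseudo-replication (above) reproduces
  standard practice in device-validation tables; treat its p-values
  accordingly.
- The WSCV estimator is one defensible reconstruction of "within-subject
  CV of the differences"; published studies rarely state theirs exactly.
- Synchronization assumes a constant integer lag per recording; clock
  drift would need piecewise estimation.
- The deterministic reference screen approximates, but cannot replicate,
  human visual screening of irregular criterion data.
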