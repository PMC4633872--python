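# Methods

## Scientific setting

During steady fixation the eyes produce small rapid movements (fixational
saccades, or microsaccades) at a baseline rate of roughly 1–2 per second.
A visual transient triggers a stereotyped biphasic modulation of that rate:
a brief *inhibition* (rate drop) at ~100–250 ms followed by a *rebound*
(rate elevation) at ~350–500 ms before a return to baseline.  The depth of
the inhibition and the gain of the rebound grow with stimulus contrast, and
they do so over the same contrast range in which the observer's perceptual
detection performance rises from chance to ceiling.  `fixsig` implements
the full analysis chain that exploits this coupling to estimate an
individual's contrast-detection threshold from passive fixation data alone,
together with a synthetic-data generator that stands in for raw
eye-tracking recordings (which are not publicly available for this class of
experiment).

## Synthetic data generator (`fixsig.simulate`)

**Rate model.**  Saccade onsets form an inhomogeneous renewal process with
rate `baseline_rate * m(t; c)`.  The modulation profile is a unit baseline
with two Gaussian bumps,

```
m(t; c) = 1 − a(c) · G(t; μ_inh, σ_inh) + b(c) · G(t; μ_reb, σ_reb)
```

with defaults μ_inh = 180 ms, σ_inh = 80 ms, μ_reb = 420 ms, σ_reb =
120 ms.  Because the bumps overlap (the tails interact at the default
latencies), the coefficients (a, b) are obtained from the 2×2 linear system
that makes the profile pass *exactly* through `1 − d(c)` at μ_inh and
`1 + g(c)` at μ_reb; d and g are the nominal depth and gain.  The profile
is clipped at zero.  Depth and gain share a single logistic drive in log10
contrast, `L(c) = 1 / (1 + exp(−(log10 c − μ)/s))` with midpoint μ =
log10(2.0 %) and slope s = 0.1 by default:

```
d(c) = inhibition_depth_max · L(c)        (default max 0.5)
g(c) = rebound_gain_max · L(c)            (default max 1.0)
```

The shared drive encodes the empirical observation that inhibition and
rebound emerge at similar contrast levels; the defaults put the saturated
normalized rate minimum at 0.5 and the rebound peak at 2.0, in the middle
of the ranges reported for human observers (0.44–0.95 and 1.31–2.88).

**Sampling.**  Event times are drawn by thinning with an absolute dead time
of 50 ms, mirroring the detection-side merge window so that generated and
detected event counts are commensurable.  The hazard is dead-time
compensated, `h(t) = r(t) / (1 − r(t)·τ)`, so the *observed* rate matches
the configured one (1.5 s⁻¹ baseline ⇒ 1.8 expected events per 1.2 s
epoch), and the sampler starts in the stationary state of the baseline
renewal process (with probability r·τ an epoch begins inside a dead time).

**Kinematics.**  Each saccade is rendered in both eyes as a logistic
position ramp with amplitude drawn from N(21, 8²) arcmin (redrawn into the
detectable 3–60 arcmin band), direction weakly re-centering on the fixation
point, and peak velocity from a unit-slope log–log main sequence
(80 deg s⁻¹ at 1°, log10 scatter 0.04).  The logistic time constant is
τ = A/(4·V_peak), giving durations of 12–20 ms.  Saccades occurring inside
the inhibition window have their mean amplitude reduced by
`amplitude_dip · L(c)` (default 4 arcmin at saturation, i.e. 21 → 17).
Binocular onsets are jittered by N(0, 1 ms) between the eyes.

**Noise and artefacts.**  Slow drift is an Ornstein–Uhlenbeck process
(stationary SD 3 arcmin, time constant 4 s, implying instantaneous drift
speeds under ~1 deg s⁻¹ per axis); tracker noise is white Gaussian with SD
0.3 arcmin per axis per eye.  Blinks occur at 1 min⁻¹ with 200–400 ms
duration; the pupil channel is exactly 0 inside a blink and the position
trace is corrupted by a 2° excursion, so the blink mask genuinely matters.

**Behaviour.**  2AFC responses are Bernoulli with
`P(correct | c) = 0.5 + 0.5·L(c)`, the same drive as the oculomotor
modulation, so behavioural and oculomotor thresholds coincide by
construction (75% correct falls exactly at the midpoint contrast).  This
coupling is an assumption of the generator, made so that parameter-recovery
experiments have a well-defined ground truth.

**What the generator does not emulate.**  Trial-to-trial variability of the
signature (every trial shares one profile), latency shortening with
contrast (available via `latency_shift_max`, off by default because no
threshold estimator uses latencies), saccade-direction structure, drift
microstructure and tremor, and tracker-specific pupil dynamics.  Passing
tests therefore demonstrate correctness of the analysis chain and
calibration of the estimators under these idealized conditions, not
performance on real recordings.

## Detection (`fixsig.detection`)

Blink samples (pupil = 0) and semi-blinks (|Δpupil| > 50 units/sample) are
masked with a 200 ms buffer on each side.  Velocity is the classical
five-sample smoothed derivative `v[n] = (x[n+2]+x[n+1]−x[n−1]−x[n−2])/(6Δt)`
at 500 Hz.  Per-component thresholds are `η = 6·σ` with the median-based
estimator `σ = sqrt(median(v²) − median(v)²)`; note that for Gaussian noise
this estimator converges to 0.6745·σ_true, so the effective multiplier is
≈ 4 true SDs — this is a property of the standard algorithm, and the tests
assert the analytically correct value.  Candidates are maximal runs of ≥ 3
consecutive samples with `(vx/ηx)² + (vy/ηy)² > 1`; events shorter than
6 ms or outside 3–60 arcmin (amplitude = maximum pairwise displacement of
position within the run) are discarded; events separated by < 50 ms are
merged transitively with amplitude and peak velocity recomputed over the
union; and finally events must overlap in time across the two eyes
(half-open intervals, greedy earliest-overlap matching), with binocular
parameters the mean of the two eyes.  Thresholds are estimated once per
recording over unmasked samples.

## Rate signature (`fixsig.signature`)

Event onsets (each counted once) are binned at 2 ms in a fixed epoch of
−100…+1100 ms around stimulus onset; trials whose epoch overlaps the blink
mask for ≥ 100 ms or extends past the recording are discarded.  The mean
per-bin count times the 500 Hz sample rate gives saccades/s.  Smoothing is
Savitzky–Golay with a 102 ms (51-bin) window, polynomial order 2 (the
lowest order that preserves trough and peak curvature), mirrored edges, and
clipping at zero.  Confidence bands are percentile bootstrap across trials
(default 10 000 resamples), smoothing applied within each resample so the
band is consistent with the displayed smoothed mean.  The individual
baseline rate is the epoch-mean smoothed rate of the 0 %-contrast
condition; normalized signatures divide rate and bands by it.

## Features and thresholds (`fixsig.features`)

From the smoothed normalized signature: inhibition = minimum (and its
latency) in 0–400 ms; rebound = maximum in (inhibition latency, 800 ms];
total magnitude = rebound − inhibition; minimum saccade amplitude over
0–400 ms from the binned amplitude trace (empty bins interpolated before
smoothing).  A rebound that never exceeds baseline is reported but flagged
`low_signature`.

Feature-vs-contrast curves are fitted with a four-parameter logistic in
log10 contrast by least squares with five deterministic multi-starts; the
threshold is the fitted midpoint mapped to % contrast (the halfway point
between the fitted asymptotes).  Fits with R² < 0.3 are rejected.  Two
guards keep the midpoint identified on noisy data: the slope is bounded
above by (contrast range)/2.5 — a shallower logistic cannot resolve both
asymptotes inside the tested range, leaving the midpoint free to run away —
and callers may bound the asymptotes to the physically admissible range of
the feature (normalized rates are non-negative).  Even so, the minimum
statistic is noisy and biased: at 900 trials/contrast its null expectation
is ≈ 0.74 of baseline (minimum of ~600 smoothed noisy bins) and the bias
shrinks as a real trough emerges, which flattens the observable curve and
produces a small *positive* threshold bias — the same direction reported
for feature-based thresholds on real data.  Monte-Carlo recovery at the
default conditions lands within ±0.15 log10 units of the true midpoint in
roughly 85–90 % of replicates; occasional runaway fits on near-linear
observables are the dominant failure mode.

The behavioural psychometric function is a fixed-asymptote logistic
`P = 0.5 + 0.5·logistic((x − μ)/s)` fitted by binomial maximum likelihood
(Nelder–Mead, five starts); under this form the 75 %-correct threshold is
the midpoint.  No lapse parameter is included (the design uses contrasts
near threshold where lapses are not identifiable).  All-chance or
all-correct data are flagged out-of-range rather than extrapolated.

## Classifier (`fixsig.classifier`)

Single trials are too sparse to classify, so valid trials are partitioned
at random into disjoint samples of n = 30 trials; events are pooled per
100 ms bin across the sample (12 bins over the 1200 ms epoch), converted to
a rate, and divided by the subject's baseline rate.  For each contrast a
linear SVM with cost 1e6 separates stimulus samples from blank samples.
At this cost the problem is effectively hard margin; the fit uses
liblinear's dual coordinate descent (hinge loss, intercept_scaling = 100,
fixed random_state, iteration cap 10 000), which converges on this problem
where libsvm's SMO does not terminate in reasonable time — on converged
test cases the two agree (96 % prediction agreement, identical LOOCV
accuracy).  Accuracy is paired leave-one-out cross-validation: samples are
paired by index, the model is trained on all remaining pairs and both
left-out samples are tested.  Percent correct against log10 contrast is
fitted with a fixed-floor (50 %) free-ceiling (≤ 100 %) logistic, and the
oculomotor threshold is the contrast at 75 % correct; the bootstrap variant
re-randomizes the partition (default 1000 repeats) and averages.

The 100 ms bin width resolves inhibition and rebound while keeping counts
dense (≈ 4.5 events per bin per 30-trial sample at baseline); 12 dimensions
against 29 training pairs is the regime where the hard-margin SVM loses a
few points of accuracy relative to an ideal observer.  At the saturated
default signature (minimum 0.5, peak 2.0, baseline 1.5 s⁻¹) the empirical
class separation is d'² ≈ 11.5, an ideal-observer accuracy of ≈ 95 %;
single-subject paired LOOCV reaches ≈ 88–93 % depending on the draw.
Population asymptotes near 95 % require pooling training samples across
several observers, which `per_subject_performance` implements (training
pooled across subjects, accuracy aggregated over each subject's own test
pairs).

## Evaluation (`fixsig.evaluation`)

Threshold errors are `log10(predicted) − log10(behavioural)`; bias, root
variance (population convention, 1/n) and RMSE then satisfy
`RMSE² = bias² + root-variance²` exactly.  Log units are the natural scale:
thresholds of 1–3 % with errors of order 0.07–0.1 are only plausible on the
log10 axis.  Subjects with rejected or missing fits are excluded and
counted.

Three generalization experiments operate on event-level synthetic cohorts
(subjects differing in sensitivity midpoint; behavioural thresholds from
simulated 2AFC responses):

- **Leave-subject-out** — for each omitted subject, training pools the
  remaining subjects' samples; tested subjects inside the training pool are
  evaluated by leave-one-pair-out over their own pairs, while the omitted
  subject's samples are never seen in training (the matrix diagonal).
- **Cross-contrast** — a classifier trained at one contrast (against half
  of the blank samples) is applied unchanged at every other contrast, with
  the held-out blank half providing test blanks; the same-contrast cell
  reduces to the standard paired LOOCV.
- **Trial-count sweep** — samples are rebuilt at each trials-per-sample
  value (capped at 10 samples per subject) and the threshold comparison is
  rerun; classifiers whose accuracy curve never reaches 75 % yield a
  threshold clamped to the tested contrast range, so an uninformative
  classifier scores the error of a range-edge guess instead of dropping
  out of the average.

Cohort experiments consume generator event times directly (the lossless
detection limit) rather than rendering and re-detecting millions of gaze
samples; detection fidelity is established separately on full recordings
(≥ 90 % recovery of injected events ≥ 6 arcmin, ≤ 0.1 false events/s at
default noise).

## Problem sizes and reproducibility

Default tests and the acceptance script use 50–200 rendered trials per
condition for detection-level checks, 900 trials/contrast (event level) for
calibration and recovery, 20 replicate seeds for stochastic properties, and
reduced bootstrap counts where the full 10 000 resamples would add nothing
to the assertion.  Every stochastic stage draws from
`numpy.random.default_rng` seeded deterministically (per-stage seeds are
derived from a master seed by hashing); identical configuration and seed
give bit-identical outputs, recorded with SHA-256 digests in the run
manifest.

## Known limitations

- The generator's logistic link between contrast and the signature (and
  behaviour) is an assumption; real observers need not share one drive.
- Feature-based thresholds inherit the bias and variance of extremum
  statistics on smoothed rates; with 12 contrasts over 0.7–4 % the
  four-parameter logistic midpoint is occasionally unidentified.
- Single-subject classifier accuracy saturates below the population-pooled
  asymptote (see above), so threshold estimates carry a small positive
  bias at the default sample sizes.
- The semi-blink pupil-velocity criterion (50 units/sample) is in
  tracker-specific arbitrary units; no physical unit is claimed.
- `SVC`-style probability outputs, non-linear kernels, saccade-direction
  analyses and drift/tremor characterization are out of scope.
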