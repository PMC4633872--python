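# fixsig

Estimating visual contrast-detection thresholds from fixational eye
movements.

During steady fixation, observers make small rapid eye movements
(fixational saccades, microsaccades) at about 1–2 per second.  A visual
stimulus transiently modulates that rate: a brief **inhibition** (~180 ms
after onset) followed by a **rebound** above baseline (~420 ms), both
growing with stimulus contrast over the same range in which perceptual
detection rises from chance to ceiling.  `fixsig` turns this *rate
signature* into an objective, response-free estimate of an individual's
contrast threshold — relevant wherever psychophysical button-press
thresholds are impractical (paediatric, ageing or cognitively impaired
populations), and as an analysis framework for oculomotor studies of
stimulus sensitivity.

The package provides, as library functions and a CLI:

- **`fixsig.simulate`** — a calibrated synthetic generator of binocular
  gaze recordings (500 Hz): saccades as an inhomogeneous renewal process
  with rate `r(t) = r₀·[1 − d(c)G(t;μᵢ,σᵢ) + g(c)G(t;μᵣ,σᵣ)]`, a shared
  logistic contrast drive `L(c)` for inhibition depth `d`, rebound gain
  `g` and 2AFC behaviour `P(correct)=0.5+0.5·L(c)`, main-sequence
  kinematics, ocular drift, tracker noise and blinks.
- **`fixsig.detection`** — adaptive velocity-threshold microsaccade
  detection: blink masking (±200 ms), 5-sample smoothed derivative,
  per-component thresholds `η = 6·sqrt(median(v²) − median(v)²)`,
  elliptical criterion, ≥6 ms duration and 3–60 arcmin amplitude filters,
  50 ms merging, binocular temporal-overlap requirement, main-sequence
  verification.
- **`fixsig.signature`** — stimulus-locked rate and amplitude signatures:
  2 ms bins over −100…1100 ms, Savitzky–Golay smoothing (102 ms window),
  trial-bootstrap 95% bands, baseline-rate normalization.
- **`fixsig.features`** — inhibition/rebound magnitudes and latencies,
  minimum saccade amplitude; logistic fits over log₁₀ contrast with an
  R² < 0.3 rejection rule; binomial psychometric fits with the threshold
  at 75% correct.
- **`fixsig.classifier`** — trial down-sampling into pooled 100 ms-bin
  rate vectors, a linear support-vector classifier (cost 10⁶) per contrast
  against blank, paired leave-one-out cross-validation, bootstrap over
  partitions, and the classifier psychometric function whose 75%-correct
  point is the oculomotor threshold.
- **`fixsig.evaluation`** — bias / root-variance / RMSE of predicted vs
  behavioural thresholds (log₁₀ units, `RMSE² = bias² + rootvar²`), plus
  leave-subject-out, cross-contrast and trials-per-sample generalization
  experiments on synthetic cohorts.

See `docs/methods.md` for the model, parameter meanings and defaults,
numerical choices and known limitations.

## Worked example

Simulate a session (7 contrast levels including a 0% blank, 240 passive +
60 response trials per level), detect saccades, build signatures and
estimate the threshold both ways:

```bash
python - <<'PY'
from fixsig import SimulationConfig
SimulationConfig(contrasts=[0.0, 0.7, 1.0, 1.4, 2.0, 2.8, 4.0],
                 n_passive=240, n_response=60).to_json("cfg.json")
PY
fixsig run --config cfg.json --out demo/ --seed 42 --boot 200
fixsig features --signatures demo/ --out demo/feat.csv
fixsig classify --events demo/events.csv --trials demo/trials.csv \
                --out demo/curve.csv --per-sample 30 --boot 1 --seed 3
```

which prints

```
completed stages: simulate, detect, signature, features, classify
inhibition-feature threshold 1.674% (R^2=0.431)
classifier threshold 2.747%
```

and writes `demo/curve.csv`:

```
contrast,percent_correct
0.7,50.0
1.0,43.75
1.4,56.25
2.0,62.5
2.8,75.0
4.0,87.5
```

Reading the numbers: the generator's true sensitivity midpoint is 2.0%
contrast.  Classifier accuracy sits at chance (~50%) for sub-threshold
contrasts and rises sigmoidally to ~88% at 4%; the 75%-correct point of
the fitted curve gives an oculomotor threshold of 2.75%, and the logistic
fit of the inhibition-magnitude feature gives 1.67% — both bracket the
true 2% with the scatter expected at 240 trials per contrast (the study
design uses 900, which roughly halves the threshold error).  A
`manifest.json` in the output directory records the config, per-stage
seeds and SHA-256 digests of every file; re-running with the same config
and seed reproduces them bit for bit.

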