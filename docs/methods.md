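# Methods

## The waveform model

A PPG beat is treated as the superposition of one incident wave (cardiac
ejection) and one reflected wave (impedance mismatch at arterial
bifurcations), each a Gaussian in time. This two-component pulse
decomposition is deliberately minimal: it captures the systolic peak, the
dicrotic notch and the diastolic peak with six parameters, makes the
inflection point (the crossing of the two components) well defined, and
is exactly invertible on synthetic data. Richer morphologies (3–5
component decompositions, secondary reflections) are out of scope.

"Fitting a Gaussian mixture" here means constrained nonlinear
least-squares fitting of a sum of two Gaussian *functions* to the sampled
waveform — the beat is a deterministic curve, not a sample of draws, so
probabilistic EM on observations would be the wrong primitive. The fit
runs on the beat's own 1000-point grid with analytic Jacobian, bounds
(amplitudes ≥ 0, centres inside the beat, widths positive), a
deterministic data-driven start (incident centre at the global maximum,
reflected centre at the later of max + 0.2·duration or the largest late
local maximum, widths duration/8, amplitudes read off the waveform) plus
four seeded jittered restarts. Restarts stop early when a fit already
reaches residual RMSE 1e-6 — clean beats converge on the first start, so
the restart budget is spent only on hard beats. Components are relabelled
after every fit so the earlier-centred one is "incident". An optimizer
failure is reported as `converged=False` and the quality gate drops the
beat; no exception propagates.

On noiseless two-Gaussian beats evaluated directly on the fitting grid
the six parameters are recovered to machine precision (the acceptance
script reports the worst case over 100 random beats, typically ~1e-14
relative). Through the *full* preprocessing path the recovery is instead
limited to roughly the size of two small systematic effects: min-max
normalization rescales amplitudes by 1/(max−min), where max exceeds the
incident amplitude by the component overlap at the peak, and linear
interpolation plus the 10 Hz low-pass slightly widen the fitted
components. Both effects are fractions of a percent with the default
morphology, are common to every beat of a recording, and cancel in the
cohort-level correlation and regression analyses.

## Preprocessing choices

* **Filter**: linear-phase Hamming-window FIR, passband 0.5–10 Hz, tap
  count chosen for a ≤ 0.3 Hz transition at the low edge; applied by
  centred convolution with reflected padding so group delay is fully
  compensated. A 0.2 Hz baseline wander is attenuated > 20 dB; a 2 Hz
  pulse harmonic passes within 1 dB.
* **Onset detection**: maximal-upslope points are located first — the
  systolic upstroke is several times steeper than any diastolic rise, so
  candidates are gated at 45% of the 85th-percentile upslope (a
  percentile, not the maximum, so one surged beat cannot mask the rest)
  with a refractory of 0.55 autocorrelation periods. Each onset is the
  argmin of the valley within 0.4 periods before its upstroke. On clean
  synthetic recordings at 250 Hz detected onsets sit within ±3 samples of
  the generator's ground truth.
* **Rejection thresholds**: a beat is dropped when its duration or
  peak-to-peak amplitude deviates more than 25% (configurable) from the
  recording median, or when a local maximum after the first systolic peak
  exceeds that peak. The 25% default makes the "irregular interval or
  amplitude" rule explicit and testable.
* **Conventions**: sample indices are 0-based; segments are half-open
  [onset_i, onset_{i+1}); times are indices/fs in seconds. Resampling to
  1000 points uses the grid t_j = j·duration/1000, so a 1000-sample beat
  maps onto itself; the original duration is kept on the normalized beat
  because all timing information would otherwise be lost to the fixed
  grid.

## Features

Skewness and kurtosis of a waveform are computed as the standardized
third and fourth central moments of *time*, weighting each instant by the
waveform value (trapezoid quadrature) — the waveform acts as an
unnormalized density over the beat. This captures the left/right
asymmetry of the pulse shape that changes with arterial stiffening; the
alternative (sample moments of the amplitude values) measures the
amplitude histogram instead and was rejected. Kurtosis is non-excess
(a Gaussian scores 3) everywhere.

A Gaussian component has unbounded support, so its "time period" is
defined as the width of the interval where it exceeds 1% of its peak
(2·sqrt(2 ln 100)·σ ≈ 6.07σ), clipped to the beat window — σ-proportional
and directly testable. The inflection point is the first crossing of the
two component waveforms between their centres (bisection to 1e-6 s); its
"area" is the area under the reconstructed pulse from the beat onset to
the crossing time, the one reading of "area of first inflection" that is
well defined for every gated beat. Component peak amplitude is the
amplitude parameter itself (the Gaussian maximum).

Note that the systolic peak amplitude of a min-max-normalized beat is
identically 1; the feature is retained for structural completeness (its
differences with other amplitudes still vary) and the scaler handles the
zero-IQR column by centring only.

Per-beat 78-vectors are aggregated per subject by the element-wise
median — robust to the occasional residual bad beat; the count of
contributing beats is recorded. A subject with no accepted beats is
excluded with a logged reason.

## The synthetic cohort

The generator emulates: beats that are exact two-Gaussian sums; beat-to-
beat interval and amplitude jitter (3% sd each); additive white noise
(default sd 0.01 of the normalized amplitude); sinusoidal baseline wander
at 0.2 Hz (default amplitude 0.05 — below the passband edge, so the
filter must remove it); and, at a default rate of 2% per beat, grossly
irregular beats whose interval or amplitude is inflated 2.2× to exercise
the rejection stage. Sampling rates are restricted to 125/250 Hz.

Age trends are linear in the parameter means with Gaussian between-
subject jitter: the reflected amplitude falls by 0.004 per year around
0.45 at age 50 (sd 0.05), and the reflected width by 0.0003 per year —
so both the reflected peak amplitude and the reflected area decrease
monotonically with age, the direction the regression must recover. Pulse
centres are not independent parameters: each pulse is anchored to start
at 0.6% of its incident peak and to decay to amplitude 0.02 at the beat
end, as real pulses rise from and return to the diastolic baseline. This
keeps consecutive beats joining at a sharp, well-defined minimum (which
is what makes sub-sample onset accuracy meaningful) and implies the
reflected peak time drifts mildly later with age.

What the simulator does **not** emulate: motion artifacts, sensor
decoupling, multi-site morphology differences, respiratory modulation,
or any nonlinearity between age and pulse shape. Passing the end-to-end
tests therefore shows that the pipeline recovers a planted monotone
age signal through realistic noise, segmentation and fitting — not that
it reproduces clinical accuracy on real cohorts, whose headline numbers
are inherently out of reach without the original recordings.

## The regressor

The network is 78 → 128 (ReLU, inverted dropout p = 0.5) → 1, He-uniform
initial weights, MAE loss, Adam (lr 0.001, β = 0.9/0.999), batch 32,
early stopping on validation MAE with patience 50 and restoration of the
best (earliest on ties) epoch, at most 500 epochs by default. It is
implemented directly in numpy; one seed drives initialization, shuffling
and dropout masks, so runs are bit-reproducible on one thread. The output
bias is initialized at the training-target mean: with MAE loss and a
small Adam step the output otherwise spends thousands of steps crawling
toward the mean age before learning any structure.

Evaluation is leave-one-out: for each held-out subject the remaining
subjects are split 8:2 into training and validation, stratified by age
decade (decades with fewer than two subjects are merged with a
neighbour); the robust scaler — per-feature (x − median)/IQR, zero-IQR
columns scaled by 1 with a warning — is fit on the training portion only.
Nothing outside a fold's own training/validation rows influences that
fold's scaler, weights, or stopping epoch; a dedicated test perturbs the
held-out row and asserts the fold's weights are unchanged.

Bland–Altman limits use the sample standard deviation (n−1) of the
est − true differences: mean ± 1.96 sd.

## Problem sizes and defaults used in the shipped runs

The end-to-end evaluation runs 200-subject cohorts with 12 s recordings
at 125 Hz (~12 beats/subject) and an epoch budget of max 300 with
patience 50 — enough for the validation loss to plateau on these cohort
sizes while keeping a five-seed evaluation in the minutes range. Typical
results: LOOCV Pearson r ≈ 0.83–0.87, RMSE ≈ 9–10 years, reflected-wave
feature–age correlations ≈ −0.8.

## Known limitations

* The two-Gaussian model cannot represent beats with prominent secondary
  reflections; such beats fail the 0.9-correlation gate and are dropped
  rather than modelled.
* Onset accuracy is quoted for clean signals; under heavy noise the
  argmin valley estimator degrades gracefully but without a guarantee.
* The 1% component-support threshold, the inflection-area definition and
  the median aggregation are package conventions — defensible, tested,
  but not unique readings of the underlying feature names.
* Min-max normalization couples nominally independent features: because
  the normalizing range depends (weakly) on the reflected wave, features
  such as the incident peak amplitude can acquire small but statistically
  strong age correlations on synthetic cohorts even when no trend was
  planted in them. Only the planted reflected-wave trends are treated as
  sign contracts.
* With ~150 training subjects the network sits well inside the
  overparameterized regime; dropout and early stopping keep it honest,
  but confidence intervals on the LOOCV statistics are not provided.
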