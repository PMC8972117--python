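# vascage — vascular-aging estimation from PPG pulse decomposition

`vascage` estimates a subject's vascular age from a single-channel
photoplethysmogram (PPG). Arterial stiffening with age changes the shape
of the peripheral pulse — most visibly, it weakens the reflected wave
returning from arterial bifurcations — so the morphology of each beat
carries information about chronological age. The package is aimed at
physiological-signal researchers who want a fully testable, end-to-end
reference pipeline: every stage can be validated against a built-in
synthetic cohort simulator with known ground truth, so no clinical
recordings are required.

## The method

1. **Preprocessing.** The raw signal is bandpass filtered (linear-phase
   FIR, 0.5–10 Hz), pulse onsets are detected as the valley minima
   preceding each systolic upslope, beats are segmented on inter-onset
   spans, arrhythmic or malformed beats are rejected against
   recording-level medians, and each surviving beat is linearly
   interpolated onto 1000 samples and min-max normalized to [0, 1].

2. **Pulse decomposition.** Each beat x(t) is modelled as the sum of an
   incident and a reflected Gaussian wave,

   x(t) ≈ a_i exp(−(t−μ_i)²/2σ_i²) + a_r exp(−(t−μ_r)²/2σ_r²),  μ_i < μ_r,

   fitted by bounded nonlinear least squares. A beat enters the analysis
   only if the reconstruction correlates with the original at r ≥ 0.9 and
   the incident peak dominates the reflected peak (a_i > a_r).

3. **Features.** 26 basic features (peak amplitudes/times, areas,
   durations, time-weighted skewness and kurtosis of the incident wave,
   reflected wave, their crossing point, the reconstructed pulse and the
   original pulse) plus 52 fixed ratios/differences of them — 78 features
   per beat, aggregated per subject by the element-wise median.

4. **Regression.** A single-hidden-layer neural network (78 → 128 ReLU
   nodes with dropout 0.5 → 1 output; He-uniform init, MAE loss, Adam at
   lr 0.001, early stopping with patience 50, robust median/IQR input
   scaling) is evaluated by leave-one-out cross-validation with an 8:2
   age-stratified train/validation split inside every fold. Agreement is
   summarised by RMSE, Pearson r, R², and Bland–Altman 95% limits
   (mean difference ± 1.96 sd).

## Worked example

```python
from vascage import PipelineConfig, run_pipeline, feature_age_correlations
from vascage.ann import AnnConfig

cfg = PipelineConfig(n_subjects=40, recording_duration=15.0, seed=7,
                     ann=AnnConfig(max_epochs=300, early_stopping_patience=50))
table, res = run_pipeline(cfg, "demo_out")
print(res.summary())
```

prints (about a minute on one CPU):

```
Vascular age estimation - leave-one-out cross-validation
==========================================================
subjects                         40
RMSE (years)                   9.06
Pearson r                     0.824   (p = 6.67e-11)
R-squared                     0.675
Bland-Altman mean diff        -0.55  years
95% limits of agreement      -18.49 .. 17.40 years
```

Each of the 40 synthetic subjects was held out once; the network
estimated their age from the 78 pulse-shape features with a
cross-validated error of ~9 years and a strong estimated-vs-true age
correlation. The feature table confirms the physiological signal the
simulator planted — the reflected-wave amplitude and area fall with age:

```python
corr = feature_age_correlations(table, table["age"]).set_index("feature")
print(corr.loc[["REF_peak-amp", "REF_area"], "pearson_r"])
# REF_peak-amp   -0.8122
# REF_area       -0.8238
```

The same pipeline is scriptable from the shell:

```bash
vascage synth --n 40 --seed 7 --out demo/raw          # signals + ground truth
vascage featurize --in demo/raw --out demo/features.csv
vascage evaluate --features demo/features.csv --out demo/eval
```

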