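# pshwatch

Heart-rate-variability (HRV) characterization and prediction of **paroxysmal
sympathetic hyperactivity (PSH)** — the episodic "autonomic storms" (surging
heart rate, blood pressure, sweating, posturing) that complicate severe
acquired brain injury.  The package is aimed at physiological-signal
researchers who want a tested, reusable version of the full analysis chain:
from single-lead ECG or a beat-annotated RR series to spectral, entropy, and
wavelet-trend features, and on to an RBF-kernel support-vector machine that
separates PSH episodes from heart-rate-matched control (noPSH) events up to
20 minutes before clinical onset.

Because storm recordings are scarce and not shareable, a first-class
synthetic episode generator reproduces the statistical structure the
analysis relies on, so every stage is testable end to end.

## The analysis

Each annotated episode covers 1800 s split into three adjacent 600-s
windows: Pre20 = [onset−1200, onset−600), Pre10 = [onset−600, onset), and
Event = [onset, onset+600).  Per window the pipeline computes:

- **Time domain** — mean HR, max HR (10-s rolling mean), and SDNN, the
  standard deviation of artifact-free NN intervals.
- **Frequency domain** — the RR tachogram is cubic-spline resampled to
  4 Hz, quadratically detrended, and analyzed with Welch's method (150-s
  Hann segments, 50% overlap).  Band powers are integrated over
  VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz, and HF 0.15–0.5 Hz; their natural
  logs (raw powers are heavily right-skewed) plus the LF/HF and
  VLF/(LF+HF) ratios are reported.
- **Complexity** — multiscale sample entropy on the beat-domain RR series:
  SampEn(m=2, r=0.2·SD, Chebyshev distance, self-matches excluded) on
  coarse-grained series at scales 1–10, summarized as
  CI_s = ΣSampEn(scales 1–5) and CI_l = ΣSampEn(scales 6–10).
- **Wavelet trends** — an analytic Morlet CWT (ω₀ = 6, 12 voices/octave)
  over the full episode yields VLF/LF/HF band-power time courses whose
  ordinary-least-squares slopes (with SE, F-ratio, p, R², 95% CI)
  quantify the gradual collapse of autonomic variability.

Group contrasts use Shapiro–Wilk checks and paired / independent t-tests at
a Bonferroni-corrected alpha of 0.05/44 ≈ 0.001.  The classifier ranks the
HRV features by random-forest importance, tunes an RBF-SVM over a 10×10
log-spaced grid (C ∈ [0.5, 10], gamma ∈ [0.01, 10]; 100 models) with
stratified tenfold cross-validation (per-fold standardization, pooled
out-of-fold confusion matrix), freezes the Event-window hyperparameters for
the earlier windows, and quantifies each feature's contribution by
leave-one-feature-out ablation.  A small utility scores the PSH Assessment
Measure (six 0–3 Clinical Features Scale items + eleven binary Diagnosis
Likelihood Tool items; combined ≥ 19 ⇒ probable PSH).

## Worked example

```python
import numpy as np
from pshwatch import synthetic_data as sd, episode_pipeline as pipe, classifier as clf

# one synthetic storm episode
episode = sd.generate_rr_series(sd.default_psh_spec(seed=1))
beats = episode.to_beat_series()
_, windows = pipe.segment_windows(beats, onset=1200.0)
for name, wbeats in windows.items():
    fv = pipe.extract_features("demo", "PSH", name, wbeats)
    print(f"{name:>6}: mean HR {fv.mean_hr:6.1f} b/min   "
          f"lnHF {fv.ln_hf:5.2f}   CI_s {fv.ci_short:5.2f}")

# cohort-level classification
features = pipe.cohort_features(n_psh=24, n_nopsh=24, seed=1)
event = features[features.window == "Event"]
selected, _ = clf.select_features(event, seed=1)
search = clf.grid_search(event, selected, seed=1)
res = clf.crossvalidate(search.best, event, selected, seed=1)
m = res["validation"]
print(f"selected features: {selected}")
print(f"best config: C={search.best.cost_c:.2f}, gamma={search.best.gamma:.3f}")
print(f"event-window validation: sensitivity {m.sensitivity:.2f}, "
      f"specificity {m.specificity:.2f}, balanced accuracy {m.balanced_accuracy:.2f}")
```

prints

```
 Pre20: mean HR   97.8 b/min   lnHF  5.36   CI_s  7.21
 Pre10: mean HR  104.6 b/min   lnHF  4.26   CI_s  5.77
 Event: mean HR  120.9 b/min   lnHF  1.36   CI_s  2.91
selected features: ['ln_hf', 'ci_short', 'ln_lf', 'sdnn']
best config: C=10.00, gamma=0.010
event-window validation: sensitivity 1.00, specificity 1.00, balanced accuracy 1.00
```

Reading the per-window rows: approaching the storm the heart rate climbs
from ~98 to ~121 b/min, high-frequency (parasympathetic) power collapses
(lnHF 5.4 → 1.4), and short-scale complexity falls (CI_s 7.2 → 2.9) —
the entropy decline is already visible ten minutes before onset, which is
what gives the classifier pre-onset discriminative power.

A thin CLI wraps the same functions:

```sh
pshwatch simulate out/ --n-psh 24 --n-nopsh 24 --seed 0   # RR CSVs + manifest
pshwatch features features.csv --seed 0                    # per-window table
pshwatch trends trends.csv --seed 0                        # slope table
pshwatch classify metrics.csv --window event --seed 0 --ablate
```

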