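# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pshwatch`, and what the synthetic-data tests do and do not show
about real recordings.

## The synthetic episode generator

### Beat generation

Beats come from an integrate-and-fire (IPFM-style) model: an instantaneous
RR period T(t) is built on an 8 Hz grid, the rate 1/T(t) is integrated, and
a beat fires at every integer crossing.  This keeps beat times, RR
intervals, and ECG template placement mutually consistent, which the
detection round-trip tests rely on.  T(t) is clamped to the physiological
range 250–2000 ms.

The period is the sum of four components:

1. **Baseline ramp.**  60/HR(t), with HR(t) a logistic sigmoid from
   `hr_baseline` to `hr_peak` centered 120 s *before* the annotated onset
   with time constant 150 s.  This timing makes the Pre10 window carry a
   partial pre-onset rise and spreads the smooth RR decline across the
   event window, reproducing the window means a storm shows
   (97 → ~104 → ~121 b/min for the default PSH parameters; 95 → ~100 for
   noPSH).  A sharper or onset-centered transition would concentrate the
   whole rise into a step at the window boundary, which is not what storm
   tachograms look like.
2. **Band oscillators.**  One sinusoid per HRV band at fixed in-band center
   frequencies (VLF 0.02, LF 0.06, HF 0.25 Hz) with linearly decaying
   amplitude envelopes, clipped at zero.  Default initial amplitudes are
   45/30/25 ms of RR deviation.  The LF oscillator sits in the lower half
   of its band because the storm tachogram is dominated by slow, smooth
   modulation; a 0.1 Hz oscillator would decorrelate adjacent beats and
   misrepresent the low-complexity character of event windows.
3. **Amplitude decay.**  Defaults (s of RR per s): PSH −1.1e−5 (VLF),
   −1.3e−5 (LF), −1.6e−5 (HF); noPSH −7e−6, −7e−6, −8e−6.  These encode
   the qualitative structure the trend analysis detects: every band's
   power declines in both conditions; the PSH decline is steeper in every
   band; the initial *power* slopes order VLF > HF > LF for PSH and
   VLF > LF ≳ HF for noPSH; and the HF *relative* loss exceeds the LF one
   under PSH (≈94% vs ≈66% over 1800 s) — parasympathetic withdrawal
   outpaces LF loss.  Because VLF decays least in relative terms, the
   VLF/(LF+HF) ratio rises toward and during PSH events.  Magnitudes are
   modeling choices, not claims about any particular patient.
4. **Modulation noise.**  A `noise_mix`-weighted blend of white (mix = 1)
   and 1/f (mix = 0) noise, SD 15 ms at t = 0, with its own linear decay
   (−8.7e−6 s/s for PSH, −1e−6 for noPSH).  The steep PSH noise decay is
   the generator's model of *decomplexification*: during the storm the
   irregular beat-to-beat variability collapses while the deterministic
   surge dominates, which is what drives SampEn (and hence CI_s, CI_l)
   down in PSH event windows, detectably already in Pre10.  PSH noise is
   1/f-dominated (mix 0.2), noPSH whiter (mix 0.6).

### Cohort draws

Between-episode variability uses a *common* lognormal gain (σ = 0.5)
applied to all oscillator amplitudes **and** the noise SD, plus per-band
lognormal jitter (σ = 0.3) and baseline/surge HR jitter (SD 8 and
6 b/min).  The common gain reproduces the strong right skew of raw band
powers across events while leaving the modulation *structure* — which the
scale-free entropy measures see — condition-typical.  Decay slopes scale
with the drawn amplitude (times lognormal σ = 0.2), so what varies between
episodes is each band's decay timescale, not its endpoint: a storm
extinguishes respiratory sinus arrhythmia regardless of its baseline
amplitude.

### What the generator does not emulate

No ectopy or artifact bursts in the default cohorts (artifact correction is
exercised on constructed fixtures), no blood-pressure, temperature, or
posture channels, no patient-specific tachogram morphology, and no
pathological ECG morphologies (the ECG template is a fixed Gaussian
P-QRS-T).  Passing tests therefore show the *pipeline* is correct and that
the method separates conditions with the assumed statistical structure —
they do not validate the clinical effect sizes, which require real
recordings.

## Preprocessing

R peaks: the Pan–Tompkins cascade (5–15 Hz band-pass, derivative, square,
150-ms moving-window integral, adaptive dual thresholds with search-back,
200-ms refractory), with zero-phase filtering and a centered integration
window so no stage introduces lag; candidates are refined to the raw-signal
maximum within ±25 ms, which also makes detection invariant to a constant
voltage offset.

Artifact correction flags intervals deviating more than 25% (configurable)
from an 11-interval centered rolling median.  In the default interpolation
mode, flagged intervals are replaced by cubic-spline values over accepted
intervals and each contiguous flagged run is rescaled so its RR sum equals
the original run duration — accepted beat times and total duration are
preserved exactly, and an early ectopic beat (400 + 1200 ms around an
800-ms rhythm) repairs to ≈800 + 800 ms.  An exclusion mode leaves the
values in place and lets time-domain statistics skip flagged intervals;
whether excluded or interpolated beats feed SDNN is a genuine degree of
freedom in practice, so both are provided (interpolation is default).
Series with > 20% flagged intervals are marked low-quality but processed.

Respiration (EDR) uses the per-beat R-wave amplitude series — one of
several published EDR schemes, chosen because the generator modulates R
amplitude directly — spline-resampled to 4 Hz; the rate is the dominant
spectral peak in 0.1–0.7 Hz, reported only when it rises 5× above the
median spectral level.

## Spectral and entropy choices

- Welch taper/overlap are Hann and 50% (not uniquely determined by the
  window length; exposed in `PipelineConfig`).
- Band edges are half-open [low, high) except HF closes at 0.5 Hz, so no
  bin is counted twice.
- With 600-s windows the VLF floor (0.0033 Hz) admits only ~2 cycles; the
  VLF estimate at the band floor is correspondingly high-variance.  This
  is inherent to the window length, not hidden by the implementation.
- ln of a band power below 1e−12 ms² (numerically zero, e.g. a constant
  window) is reported missing rather than −∞ so downstream statistics skip
  it.
- "Max HR" is the maximum 10-s rolling-mean heart rate (robust to
  single-beat spikes); the raw per-beat maximum is reported alongside.
- MSE runs on the artifact-corrected, non-interpolated beat-domain RR
  series — entropy on a 4 Hz spline grid inflates regularity.  The
  tolerance r = 0.2 × SD of the scale-1 series is fixed across scales
  (per-scale renormalization available by flag; it changes results
  materially, so it is never silent).  SampEn with zero matching pairs is
  missing, never capped.  A constant series has SampEn 0 by convention at
  every scale.
- Sample entropy counts template pairs with a KD-tree under the Chebyshev
  metric; the test suite holds it to exact agreement with an independent
  O(N²) brute-force count.

## Wavelet trends

PyWavelets' complex Morlet `cmor2.0-0.95493` is the ω₀ = 6 analytic Morlet
(envelope exp(−t²/2)).  Frequencies are log-spaced over 0.0033–0.5 Hz at 12
voices per octave.  Squared coefficients are scaled by 2·Δt·√(2πB) so that
a sinusoid of amplitude a integrates to a²/2 across frequency (verified
numerically to ~1%); with RR in seconds the map carries s²/Hz and the
band-integrated time courses carry s².  The cone of influence excludes, per
frequency, samples within one envelope e-folding time (≈1.35/f seconds) of
an edge; trend fits use COI-interior samples by default (a flag restores
the naive fit).  For an 1800-s episode this leaves ≈980 s of usable VLF
samples; 600-s windows leave none at the VLF floor, which is why trends are
fitted on full episodes.

Trend inference is ordinary least squares of band power on time at the 4 Hz
sample rate, with t-based 95% CIs at n−2 degrees of freedom.  Serial
correlation of wavelet power is deliberately ignored — the reported SEs
describe the conventional regression summary, not an honest independent-
sample inference — and a block-bootstrap alternative is intentionally out
of scope for the default output.  A constant series returns slope 0 and
R² = 0 (the 0/0 case resolved by convention).

## Statistics and classification

The Bonferroni divisor defaults to 44 planned comparisons (alpha ≈ 0.001);
the standard battery runs PSH-vs-noPSH per window (independent) and
adjacent-window pairs within condition (paired) for each of the ten
features.  Non-normal groups (Shapiro–Wilk p < 0.05) are flagged but still
tested parametrically, matching how such batteries are conventionally
reported.

The SVM's candidate features are SDNN, lnVLF, lnLF, lnHF, LF/HF, CI_s,
CI_l — heart rate itself is deliberately excluded so the model captures
information beyond the tachycardia.  Hyperparameters come from a 10×10
log-spaced grid (a seeded log-uniform random search over the same ranges is
available); "best" means maximal validation balanced accuracy with ties
broken toward smaller C then smaller gamma.  Standardization is fitted
inside each training fold; validation metrics pool the out-of-fold
confusion matrix (fold-averaging by flag).  Event-window hyperparameters
are frozen and reused for Pre10/Pre20 to avoid per-window adaptation.
Etiology can be carried as an optional one-hot feature but is excluded by
default.  Ablation tables report balanced-accuracy drops and overall /
per-class misclassification for each left-out feature; the reference
predictor set for ablation comparisons is {lnVLF, lnHF, CI_s, CI_l}.

## Problem sizes in the test suite

The default test run uses 24 + 24-episode cohorts for the end-to-end checks
(ten cohort seeds for the ablation-direction rate), 20 seeded replicates
for stochastic properties (Parseval recovery, MSE structure, detection at
10 dB SNR), 100 seeded runs for CI coverage at the −5e−6 s²/Hz·s operating
point, and 30 mixed synthetic signals for the CWT-vs-Welch agreement —
sizes chosen so every stochastic property is tested at meaningful power
while the whole suite stays fast.

## Known limitations

- The generator's effect sizes are design choices that satisfy the
  documented qualitative structure; real-cohort effect sizes will differ.
- OLS trend SEs ignore serial correlation (see above).
- noPSH "onsets" have no operational definition beyond an annotated HR
  rise; the pipeline requires an explicit onset and never infers one.
- The PSH-AM scorer implements the published band edges (CFS > 13 severe,
  combined ≥ 19 probable) with conventional lower bands; it is a
  bookkeeping utility, not a clinical instrument.
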