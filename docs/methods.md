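# Methods

This note documents the models, numerical choices and limitations of the
`fibwave` analysis chain. It is the package's own account of its science;
every number quoted here is computed by the test suite or the acceptance
script, not asserted from memory.

## Signal model of the synthetic f-waves

The atrial signal is a harmonic series anchored at a dominant frequency
`f0`:

    x(t) = [ Σ_h a_h sin(2π h φ(t) + φ_h) ] · (1 + m_a sin(2π f_a t)) + ε(t)

with amplitudes `a_h = a_0 exp(−γ (h−1)/2)`, so the *power* of harmonic
h+1 is `exp(−γ)` times that of harmonic h and the generator's
`harmonic_log_decay` parameter is, by construction, the ground-truth
harmonic exponential decay γ that the spectral stage estimates from the
PSD peaks at `f0` and `2 f0`. The instantaneous phase integrates
`f0 + Δf sin(2π f_m t)` (frequency modulation, default depth 0.15 Hz in
cohort simulations), a slow multiplicative envelope models amplitude
modulation, and ε is white noise. Harmonic phases are drawn uniformly per
realization; no PSD-based feature depends on them.

Defaults: `a_0 = 0.05` mV (a typical V1 f-wave amplitude; no amplitude
statistics are published for this cohort, so the value is a plausible
physiological choice exposed in the configuration), three harmonics,
`f0 ∈ [3, 12]` Hz enforced.

The ventricular model is a five-Gaussian QRST waveform (Q, R, S, ST
plateau, T; R amplitude 0.8 mV by default) repeated on an RR grid with
mean rate 90 bpm and 80 ms jitter, truncated so no complex overlaps its
neighbour or extends past the record end — a clipped edge complex cannot
be detected and its uncancelled upstroke would dominate the residual.
Disturbances follow the standard inventory for resting ECG: a sinusoidal
baseline drift below 0.5 Hz, a mains tone (50 Hz default, configurable
for 60 Hz grids), and white noise.

Cohorts draw per-patient `f0` and γ from group Gaussians truncated to
physiological ranges (`f0` to [3, 12] Hz, γ to positive values). The
default group parameters are the published cohort statistics — 48
"recur" patients with γ ~ N(2.20, 0.77²), f0 ~ N(5.69, 1.12²) and 103
"SR" patients with γ ~ N(2.80, 0.57²), f0 ~ N(6.14, 0.99²) — which is
also the parameterization used by the acceptance protocol. All classifier
metrics are invariant to the direction of the group difference.

### What the generator does and does not emulate

It reproduces the spectral structure the features measure (DF, harmonic
decay, modulation sidebands), realistic ventricular interference, and the
named disturbances. It does **not** model ectopic beats, electrode
artefacts, beat-morphology drift, non-stationary DF trajectories, or the
correlation structure between γ and the entropy features observed in real
patients (synthetic cohort features are drawn independently unless
derived from the same simulated signal). Passing tests therefore
demonstrate that the chain measures what it claims on signals with known
truth — not that real persistent-AF ECGs satisfy the same tolerances.

## Conditioning

* Baseline wander: 4th-order Butterworth low-pass at 0.8 Hz, applied
  forward/backward (zero phase) and subtracted. Butterworth is chosen for
  its maximally flat passband; the filter order is not prescribed by the
  method description, which fixes only the cut-off and the zero-phase IIR
  structure.
* Powerline: stationary (undecimated) wavelet transform with db4,
  decomposed deep enough that the mains frequency falls inside one detail
  level (depth 4 at 977 Hz for 50 Hz). Every detail level whose dyadic
  band contains the mains frequency or a harmonic is soft-thresholded at
  `σ sqrt(2 ln n)` with `σ = median(|d|)/0.6745`. A narrowband tone
  saturates its level's coefficient distribution and is removed entirely;
  measured on a pure 50 Hz tone the attenuation exceeds 50 dB while a
  6 Hz tone passes with <0.1% RMS error. The signal is symmetrically
  padded to a multiple of 2^depth and trimmed after reconstruction.
* High-frequency noise: 6th-order zero-phase Butterworth low-pass at
  70 Hz.
* All forward/backward filters use three seconds of odd-reflection
  padding: the default `filtfilt` padding is too short for a sub-hertz
  cut-off and would leak edge transients into the first seconds.
* Segmentation: consecutive non-overlapping 6-s segments anchored at the
  record start, at most five per patient, trailing remainder discarded.

## Ventricular cancellation (ASVC)

R peaks are detected on a 5–25 Hz band-passed, squared and 150-ms
integrated envelope. A crest-factor gate (envelope max / envelope mean
≥ 3) distinguishes beat trains from beat-free f-waves, whose envelope is
nearly flat; beats are peaks above 30% of the envelope maximum separated
by a 200 ms refractory period, refined to the local absolute maximum of
the band-passed signal. Both criteria are relative, making detection
invariant to amplitude scaling.

The cancellation template is the dominant left singular vector of the
R-aligned beat matrix (window 250 ms before to 450 ms after R), scaled by
the singular-value-weighted mean beat amplitude. Each beat is cancelled
by subtracting the template times its least-squares amplitude
coefficient; when neighbouring beats are closer than the window, the
overlap is split in proportion to the pre/post extents so windows tile
the RR interval without leaving a T-wave tail. A linear ramp
interpolating the residual's boundary mismatches removes subtraction
steps; samples outside beat windows are never modified.

Template quality is limited by f-wave leakage into the singular vector,
which shrinks as the square root of the number of beats. The pipeline
therefore cancels on the **full recording** before segmentation (the
extraction stage of the method precedes segmentation), not per 6-s
segment: with ~8 beats per 6-s segment the leakage can bias γ by up to
~1, while full-recording templates keep the end-to-end γ error within
0.18 across `f0 ∈ [4, 9]` Hz and γ ∈ [1, 2.8] with QRST, baseline, mains
and 10 dB noise present.

The residual retains sub-1-Hz remnants of the beat train's DC pedestal
(the 0.8 Hz baseline filter tracks, and subtracts, the slowly varying
mean level of the QRST train). These remnants lie entirely below the
3 Hz edge of the analysis band and do not affect any spectral feature;
residual fidelity is therefore assessed in the 3–25 Hz band, where the
correlation with the true f-wave is ≈0.96–0.97 and degrades by only
~0.01 when the QRST amplitude doubles.

## Spectral features

The Welch periodogram uses a Hamming window of 4000 samples with 3000
samples overlap at 977 Hz (the same durations in seconds at other rates)
and an FFT zero-padded to `round(fs/0.1)` points: the window's native
resolution is ≈0.24 Hz, and zero-padding reconciles the stated window
length with the stated 0.1 Hz grid.

* `f0` is the PSD argmax in the physiological 3–12 Hz search band (ties
  break toward the lower frequency); `f1` the argmax in
  `[2 f0 − 0.5, 2 f0 + 0.5]`. `W(f0)`, `W(f1)` are peak PSD bin values.
* γ = ln W(f0)/W(f1).
* O sums PSD over 1 Hz windows centred on `f0`, on the located `f1`, and
  on the argmax near `3 f0`, clipped to 3–25 Hz with overlaps counted
  once, divided by the total 3–25 Hz power.
* The LF/HF cut-off sits at `1.5 f0` — halfway between the DF and its
  first harmonic — so LF captures the DF component's shape and HF the
  harmonic structure; LF and HF partition TF exactly on the grid.
* F, S, R (α = 0.1 by default, the order reported to discriminate best),
  and C0 are computed on the band-normalized spectrum. A zero bin sends
  the flatness to 0 (geometric-mean limit); `0·ln 0 := 0` in the
  entropies; C0 is read as the ratio of summed irregular power to summed
  band power, which equals `Σ Ŵ` for a unit-power band.
* All four measures are scale-invariant and lie in [0, 1]; Rényi entropy
  is non-increasing in α. Both properties are enforced by property-based
  tests, and all four agree with independent brute-force evaluations to
  10⁻¹⁰ on 1000 random spectra.

Under these exact Welch settings a white-noise input yields mean
F_TF ≈ 0.70, S_TF ≈ 0.94, R_TF ≈ 0.99 and C0_TF ≈ 0.68: the chi-square
scatter of the averaged periodogram caps the flatness of even a
perfectly flat spectrum, which is why C0 sits slightly below 0.7.

## Statistics and classification

Continuous features: Lilliefors normality in each group and Levene
homoscedasticity at the 0.05 level choose between Student's t-test (both
hold) and the Mann–Whitney U-test (anything else, including degenerate
constant samples). No multiple-testing correction is applied — p-values
are marginal. Categorical variables use the two-sided Fisher exact test;
an empty margin returns p = 1 by convention.

LDA is fitted with pooled covariance and empirical class priors (the
SVD solver, which also handles near-singular covariance); the positive
class is AF recurrence. Evaluation pools out-of-fold scores per repeat of
a stratified patient-based 10-fold cross-validation with reshuffled
folds, computes the trapezoidal AUC via the rank statistic (exactly the
trapezoidal area, ties handled as diagonal segments), places the
operating threshold at the maximum of min(Se, Sp) — the balance rule,
with ties resolved toward sensitivity — and averages the metrics over
repeats. Results are bit-reproducible for a fixed master seed.

Two calibration facts matter for interpretation:

* a single drawn 151-patient cohort carries ≈0.045 intrinsic sampling
  noise in its AUC, which no number of CV repeats reduces — expected
  values are therefore estimated by averaging over independent cohort
  draws;
* pooled out-of-fold scores are pessimistic under the null (mean null
  AUC ≈ 0.47, not 0.50) because fold-specific intercepts scramble the
  pooled ordering; the effect is also visible as the small gap between
  the cross-validated AUC of the γ model (≈0.72) and its Gaussian closed
  form Φ(Δ/√(σ₁²+σ₂²)) ≈ 0.734.

Forward selection greedily adds the candidate that most reduces the
stratified k-fold misclassification error and stops when no addition
strictly decreases it; repeated over reshuffled folds it reports each
feature's selection frequency and the modal subset. McNemar's test uses
the continuity-corrected asymptotic statistic `(|b−c|−1)²/(b+c)` against
χ²₁, with p = 1 when the classifiers disagree on no patient.

## Problem sizes

Cohort simulations default to the study conditions (48 vs 103 patients,
five 6-s segments per patient, i.e. 30-s recordings). The acceptance
protocol evaluates the expected mean AUC over 128 independent cohort
draws, each scored by stratified 10-fold CV repeated 30 times (cohort
sampling noise, not repeat noise, dominates the estimator's variance,
so replicate cohorts buy more precision than extra repeats); end-to-end
recovery checks run one
30-s recording per grid point of `f0 ∈ {4…9}` Hz × γ ∈ {1.0, 2.0, 2.8}.

## Known limitations

* The SWT threshold function is this package's own (universal threshold
  on median-scaled coefficients); the attenuation contract, not a
  specific published threshold, defines conformance.
* The R detector assumes reasonably uniform beat amplitudes within a
  recording; a single dominant artefact could mask smaller beats.
* Per-6-s-segment cancellation is supported but yields noisier γ than
  full-recording cancellation; prefer the pipeline's default flow.
* The synthetic cohort cannot validate the multivariate models' clinical
  complementarity claims, since cross-feature correlations in real
  patients are unknown; multivariate machinery is exercised on synthetic
  correlation structures only.
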