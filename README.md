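# fibwave

Spectral-organization analysis of atrial fibrillatory waves (f-waves) for
preoperative prediction of catheter-ablation outcome in persistent atrial
fibrillation (AF).

## The problem

Catheter ablation restores sinus rhythm (SR) in persistent AF, but 40–50%
of patients relapse within a year. Before the procedure, the surface ECG
(lead V1) already carries information about how *organized* the atrial
activity is: during AF the P-wave is replaced by fibrillatory waves whose
power spectrum shows a dominant frequency (DF, `f0`, typically 4–9 Hz) and
a decaying series of harmonics. Strong harmonics — a slowly decaying
series — indicate organized atrial conduction and a better chance of
staying in SR after ablation.

`fibwave` implements the full analysis chain that turns a raw single-lead
ECG into that prediction:

1. **Conditioning** — zero-phase 0.8 Hz baseline-wander subtraction, an
   SWT (stationary wavelet transform) denoiser for 50/60 Hz mains and its
   harmonics, and a zero-phase 70 Hz low-pass.
2. **Ventricular cancellation (ASVC)** — QRST complexes are removed by
   subtracting, per beat, an amplitude-adapted template obtained as the
   dominant left singular vector of the R-aligned beat matrix, with a
   linear edge correction that keeps the atrial residual continuous.
3. **Spectral features** per 6-s segment (at most five per patient,
   averaged for subject-based analysis), from a Welch periodogram
   (Hamming window of 4000 samples, 3000 overlap at 977 Hz, zero-padded
   to a 0.1 Hz grid):
   - `f0`, `W(f0)`; first harmonic `f1`, `W(f1)` in a 1 Hz window at `2·f0`
   - harmonic exponential decay **γ = ln W(f0)/W(f1)**
   - organization index **O** — fraction of 3–25 Hz power within 1 Hz
     windows around `f0` and its first two harmonics
   - on three bands (LF = [3, 1.5·f0], HF = (1.5·f0, 25], TF = [3, 25] Hz),
     with the normalized band spectrum W̃(f):
     Wiener spectral flatness **F** (geometric/arithmetic mean),
     Shannon spectral entropy **S = −Σ W̃ ln W̃ / ln N**,
     Rényi spectral entropy **R = ln(Σ W̃^α) / ((1−α) ln N)** (α = 0.1),
     and **C0 complexity** — the share of band power in bins not exceeding
     twice the mean normalized power.
4. **Statistics** — Lilliefors/Levene screening, Student's t or
   Mann–Whitney per feature, Fisher's exact test for categorical data.
5. **Classification** — linear discriminant analysis evaluated by
   stratified patient-based 10-fold cross-validation repeated 100 times,
   with the ROC operating point balancing sensitivity and specificity,
   forward sequential feature selection, and McNemar model comparison.

The clinical recordings behind the original analysis are not public, so
the package ships a first-class synthetic-data module: a harmonic f-wave
model whose per-harmonic log power decay *is* the ground-truth γ, a
5-Gaussian QRST beat train, baseline/mains/noise disturbances, and
labelled two-group cohorts drawn from the published group statistics
(γ: 2.20±0.77 vs 2.80±0.57; f0: 5.69±1.12 vs 6.14±0.99 Hz; 48 vs 103
patients).

## Worked example

```python
import numpy as np
from fibwave import (FWaveModelParams, VentricularModelParams, generate_ecg,
                     preprocess, detect_r_peaks, cancel_qrst,
                     FWaveSignal, extract_all)

fparams = FWaveModelParams(f0_true=6.0, harmonic_log_decay=2.0, n_harmonics=3)
ecg, beats_true, clean = generate_ecg(fparams, VentricularModelParams(),
                                      duration=30.0, seed=1)
conditioned = preprocess(ecg, mains_freq=50.0)
residual = cancel_qrst(conditioned, detect_r_peaks(conditioned))
feats = extract_all(FWaveSignal(samples=residual.samples[:5862], fs=977.0))
print(f"f0 = {feats.f0:.1f} Hz, gamma = {feats.gamma:.2f}, O = {feats.O:.2f}")
```

prints

```
f0 = 6.0 Hz, gamma = 2.17, O = 0.97
```

The dominant frequency matches the generator's 6 Hz ground truth and the
measured harmonic decay recovers the simulated γ = 2.0 to within the
end-to-end tolerance of the chain (±0.3 under QRST, baseline wander,
mains and 10 dB noise); `O = 0.97` says 97% of the 3–25 Hz power sits
under the DF and its first two harmonics.

The `examples/` directory holds one short narrative script per
capability: f-wave extraction, the spectral feature set, group
statistics, outcome classification, the full pipeline, and a DF-aligned
average-spectrum plot. A thin CLI mirrors the pipeline stages:
`fibwave simulate | preprocess | extract-fwaves | extract-features |
analyze | classify | run`.

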