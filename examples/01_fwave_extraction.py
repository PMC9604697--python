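"""Extract f-waves from one synthetic AF ECG and inspect the residual.

Builds a 30-s single-lead ECG (f-waves + QRST train + baseline wander +
50 Hz mains + noise), conditions it, cancels the ventricular activity and
reports how faithfully the atrial signal was recovered.
"""

import numpy as np

from fibwave import (
    FWaveModelParams,
    VentricularModelParams,
    cancel_qrst,
    detect_r_peaks,
    generate_ecg,
    preprocess,
)

fparams = FWaveModelParams(f0_true=6.0, harmonic_log_decay=2.0, n_harmonics=3,
                           noise_sd=0.005)
vparams = VentricularModelParams(heart_rate=85.0)
ecg, truth, clean_fwave = generate_ecg(fparams, vparams, duration=30.0, seed=1)

conditioned = preprocess(ecg, mains_freq=50.0)
beats = detect_r_peaks(conditioned)
residual = cancel_qrst(conditioned, beats)

corr = np.corrcoef(residual.samples, clean_fwave.samples)[0, 1]
print(f"beats detected : {len(beats)} (ground truth {len(truth)})")
print(f"residual length: {len(residual)} samples at {residual.fs:.0f} Hz")
print(f"corr(residual, true f-wave) = {corr:.3f}")
print()
print("The residual is the atrial signal alone: a correlation near 0.9")
print("means the QRST complexes were removed without destroying f-waves.")
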