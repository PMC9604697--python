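"""Plot DF-aligned average f-wave spectra of the two outcome groups.

Optional visual helper: extracts the Welch PSD of every patient segment,
aligns each spectrum on its dominant frequency and averages per outcome
group.  Patients maintaining sinus rhythm show larger harmonic peaks
relative to the DF than those who relapse.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from fibwave import (
    CohortSimConfig,
    FWaveSignal,
    cancel_qrst,
    detect_r_peaks,
    find_dominant,
    generate_cohort,
    preprocess,
    segment_recording,
    welch_psd,
)

records = generate_cohort(
    CohortSimConfig(n_recur=10, n_sr=10, segments_per_patient=2, seed=6)
)

rel_grid = np.arange(-4.0, 14.0 + 1e-9, 0.1)  # Hz relative to the DF
group_spectra: dict[str, list[np.ndarray]] = {"recur": [], "SR": []}
for rec in records:
    conditioned = preprocess(rec.recording)
    residual = cancel_qrst(conditioned, detect_r_peaks(conditioned))
    for seg in segment_recording(rec.recording.with_samples(residual.samples)):
        psd = welch_psd(FWaveSignal(samples=seg.samples, fs=seg.fs))
        f0, wf0 = find_dominant(psd)
        aligned = np.interp(rel_grid + f0, psd.freqs, psd.W) / wf0
        group_spectra[rec.label].append(aligned)

fig, ax = plt.subplots(figsize=(7, 4))
for label, style in (("SR", "k-"), ("recur", "0.5")):
    mean_spec = np.mean(group_spectra[label], axis=0)
    ax.plot(rel_grid, mean_spec, style,
            label=f"{label} (n={len(group_spectra[label])} segments)")
ax.set_xlabel("frequency relative to DF (Hz)")
ax.set_ylabel("normalized PSD")
ax.legend()
out = Path("scratch")
out.mkdir(exist_ok=True)
fig.savefig(out / "average_spectra.png", dpi=120, bbox_inches="tight")
print(f"wrote {out / 'average_spectra.png'}")
print("The SR group's bump near +f0 (the first harmonic) sits higher than")
print("the recurrence group's: stronger harmonics, lower gamma.")
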