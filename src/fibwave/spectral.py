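"""Spectral-organization features of atrial fibrillatory waves.

Per 6-s f-wave segment the analysis estimates a Welch periodogram on a
0.1 Hz grid, locates the dominant frequency f0 (the largest PSD peak in
the physiological 3-12 Hz atrial range) and its first harmonic f1 inside a
1 Hz window around 2*f0, and derives:

* ``gamma = ln(W(f0) / W(f1))`` — the harmonic exponential decay; small
  values mean strong harmonics, i.e. organized atrial activity.
* the organization index ``O`` — the fraction of 3-25 Hz power inside
  1 Hz windows around f0 and its first two harmonics.
* four power-distribution measures on three bands (LF around the DF, HF
  covering the harmonics, TF = 3-25 Hz): Wiener spectral flatness ``F``,
  normalized Shannon spectral entropy ``S``, Renyi spectral entropy ``R``
  of order alpha (default 0.1), and the C0 complexity — the share of band
  power in bins not exceeding twice the mean normalized power.

All of F, S, R and C0 live in [0, 1]: 1 for a flat spectrum, 0 for a
single spike.  Per-patient values are arithmetic means over at most five
segments for unbiased subject-based analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import FWaveSignal

__all__ = [
    "PowerSpectrum",
    "BandDefinition",
    "NormalizedBandSpectrum",
    "SpectralFeatures",
    "welch_psd",
    "find_dominant",
    "find_first_harmonic",
    "gamma",
    "organization_index",
    "band_limits",
    "normalize_band",
    "wiener_flatness",
    "spectral_entropy",
    "renyi_entropy",
    "c0_complexity",
    "extract_all",
    "average_per_patient",
    "cohort_table",
    "FEATURE_COLUMNS",
]

#: spectral resolution of the analysis grid, Hz
GRID_STEP = 0.1

#: Welch window / overlap expressed in seconds (4000 / 3000 samples at 977 Hz)
_WINDOW_S = 4000.0 / 977.0
_OVERLAP_S = 3000.0 / 977.0

#: default dominant-frequency search band, Hz (physiological AF range)
DF_BAND = (3.0, 12.0)

#: total-frequency band of the f-wave spectrum, Hz
TF_BAND = (3.0, 25.0)

_EPS = 1e-9  # tolerance for band-edge comparisons on the 0.1 Hz grid


@dataclass(frozen=True)
class PowerSpectrum:
    """Welch PSD on a uniform 0.1 Hz frequency grid."""

    freqs: np.ndarray  #: Hz, strictly increasing, constant 0.1 Hz step
    W: np.ndarray  #: PSD values, power per Hz, >= 0
    fs: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "W", W)
        if freqs.shape != W.shape:
            raise ValueError("freqs and W must have the same shape")
        if np.any(W < 0):
            raise ValueError("PSD values must be non-negative")
        if freqs[-1] < 70.0:
            raise ValueError("frequency grid must reach at least 70 Hz")

    def band_mask(
        self, fl: float, fu: float, open_lower: bool = False
    ) -> np.ndarray:
        lower = self.freqs > fl + _EPS if open_lower else self.freqs >= fl - _EPS
        return lower & (self.freqs <= fu + _EPS)

    def band_values(self, band: "BandDefinition") -> np.ndarray:
        return self.W[self.band_mask(band.fl, band.fu, band.open_lower)]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [fl, fu] (or (fl, fu] when ``open_lower``)."""

    fl: float
    fu: float
    label: str
    open_lower: bool = False

    def __post_init__(self) -> None:
        if not self.fl < self.fu:
            raise ValueError(f"band {self.label}: need fl < fu")


@dataclass(frozen=True)
class NormalizedBandSpectrum:
    """A band PSD normalized to unit power, plus its irregular part.

    ``Wn`` sums to one over the band and is treated as a probability
    distribution.  ``T = 2/N`` (twice the mean normalized power) is the
    irregularity threshold; ``Wirr`` keeps only bins not exceeding ``T``.
    """

    freqs: np.ndarray
    Wn: np.ndarray
    N: int = field(init=False)
    T: float = field(init=False)
    Wirr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        Wn = np.asarray(self.Wn, dtype=float)
        object.__setattr__(self, "Wn", Wn)
        object.__setattr__(self, "N", int(Wn.size))
        total = Wn.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"normalized spectrum sums to {total}, not 1")
        T = 2.0 / self.N * total
        object.__setattr__(self, "T", float(T))
        object.__setattr__(self, "Wirr", np.where(Wn <= T, Wn, 0.0))


#: feature columns of the per-patient table, in reporting order
FEATURE_COLUMNS = [
    "f0", "Wf0", "f1", "Wf1", "gamma", "O",
    "F_LF", "S_LF", "R_LF", "C0_LF",
    "F_HF", "S_HF", "R_HF", "C0_HF",
    "F_TF", "S_TF", "R_TF", "C0_TF",
]


@dataclass(frozen=True)
class SpectralFeatures:
    """The full per-segment feature vector."""

    f0: float
    Wf0: float
    f1: float
    Wf1: float
    gamma: float
    O: float
    F_LF: float
    S_LF: float
    R_LF: float
    C0_LF: float
    F_HF: float
    S_HF: float
    R_HF: float
    C0_HF: float
    F_TF: float
    S_TF: float
    R_TF: float
    C0_TF: float
    alpha: float = 0.1

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}


# ---------------------------------------------------------------------------
# PSD estimation and peak location


def welch_psd(fwave: FWaveSignal | "np.ndarray", fs: float | None = None) -> PowerSpectrum:
    """Welch periodogram of one f-wave segment on a 0.1 Hz grid.

    A Hamming window of 4000 samples with 3000 samples overlap (at 977 Hz;
    the same durations in seconds at other rates) is averaged; the FFT is
    zero-padded to ``round(fs / 0.1)`` points so the grid spacing is
    0.1 Hz even though the window's native resolution is coarser.
    """
    if isinstance(fwave, FWaveSignal):
        x, fs = fwave.samples, fwave.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        x = np.asarray(fwave, dtype=float)
    nperseg = int(round(_WINDOW_S * fs))
    noverlap = int(round(_OVERLAP_S * fs))
    if x.size < nperseg:
        raise ValueError(
            f"segment of {x.size} samples is shorter than the "
            f"{nperseg}-sample Welch window"
        )
    nfft = int(round(fs / GRID_STEP))
    freqs, W = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
    )
    return PowerSpectrum(freqs=freqs, W=W, fs=fs)


def find_dominant(
    psd: PowerSpectrum, search_band: tuple[float, float] = DF_BAND
) -> tuple[float, float]:
    """Dominant frequency: the largest PSD value in the search band.

    Ties break toward the lower frequency.  Returns ``(f0, W(f0))``.
    """
    mask = psd.band_mask(*search_band)
    if not mask.any():
        raise ValueError(f"search band {search_band} is outside the grid")
    f, w = psd.freqs[mask], psd.W[mask]
    i = int(np.argmax(w))  # first maximum = lowest frequency on ties
    return float(f[i]), float(w[i])


def find_first_harmonic(psd: PowerSpectrum, f0: float) -> tuple[float, float]:
    """First harmonic: PSD argmax in the 1 Hz window centred on 2*f0."""
    lo, hi = 2 * f0 - 0.5, 2 * f0 + 0.5
    if hi > psd.freqs[-1] + _EPS:
        raise ValueError(f"harmonic window [{lo}, {hi}] exceeds the grid")
    mask = psd.band_mask(lo, hi)
    f, w = psd.freqs[mask], psd.W[mask]
    i = int(np.argmax(w))
    return float(f[i]), float(w[i])


def gamma(Wf0: float, Wf1: float) -> float:
    """Harmonic exponential decay: natural log of W(f0) / W(f1)."""
    if Wf0 <= 0 or Wf1 <= 0:
        raise ValueError("peak powers must be positive to take the log ratio")
    return float(np.log(Wf0 / Wf1))


def organization_index(
    psd: PowerSpectrum, f0: float, tf_band: tuple[float, float] = TF_BAND
) -> float:
    """Fraction of 3-25 Hz power near the DF and its first two harmonics.

    Each component contributes a 1 Hz window: centred on f0, on the located
    first harmonic, and on the PSD argmax inside [3*f0 - 0.5, 3*f0 + 0.5].
    Windows are clipped to the 3-25 Hz band and overlapping regions are
    counted once, so the index always lies in [0, 1].
    """
    centres = [f0]
    if 2 * f0 + 0.5 <= psd.freqs[-1] + _EPS:
        centres.append(find_first_harmonic(psd, f0)[0])
    lo2, hi2 = 3 * f0 - 0.5, min(3 * f0 + 0.5, tf_band[1])
    mask2 = psd.band_mask(lo2, hi2)
    if mask2.any():
        f2 = psd.freqs[mask2][int(np.argmax(psd.W[mask2]))]
        centres.append(float(f2))

    tf_mask = psd.band_mask(*tf_band)
    window = np.zeros_like(tf_mask)
    for fc in centres:
        window |= psd.band_mask(fc - 0.5, fc + 0.5)
    window &= tf_mask
    total = psd.W[tf_mask].sum()
    if total <= 0:
        raise ValueError("total 3-25 Hz power is zero")
    return float(psd.W[window].sum() / total)


def band_limits(
    f0: float, tf_band: tuple[float, float] = TF_BAND
) -> tuple[BandDefinition, BandDefinition, BandDefinition]:
    """LF / HF / TF band edges for a given dominant frequency.

    The LF/HF cut-off sits at 1.5 * f0 — approximately halfway between the
    DF and its first harmonic — so LF captures the shape of the DF
    component and HF the harmonic structure.  LF and HF partition TF.
    """
    if not 3.0 <= f0 <= 12.0:
        raise ValueError(f"f0 must lie in [3, 12] Hz, got {f0}")
    cut = 1.5 * f0
    lf = BandDefinition(fl=tf_band[0], fu=cut, label="LF")
    hf = BandDefinition(fl=cut, fu=tf_band[1], label="HF", open_lower=True)
    tf = BandDefinition(fl=tf_band[0], fu=tf_band[1], label="TF")
    return lf, hf, tf


def normalize_band(psd: PowerSpectrum, band: BandDefinition) -> NormalizedBandSpectrum:
    """Normalize the band PSD to unit power (a probability distribution)."""
    mask = psd.band_mask(band.fl, band.fu, band.open_lower)
    w = psd.W[mask]
    total = w.sum()
    if total <= 0:
        raise ValueError(f"band {band.label} has zero power")
    return NormalizedBandSpectrum(freqs=psd.freqs[mask], Wn=w / total)


# ---------------------------------------------------------------------------
# power-distribution measures


def wiener_flatness(nbs: NormalizedBandSpectrum) -> float:
    """Spectral flatness: geometric over arithmetic mean of the band PSD.

    Scale-invariant, so it is evaluated on the normalized spectrum.  Any
    zero bin drives the geometric mean — and hence F — to zero.
    """
    w = nbs.Wn
    if np.any(w == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(w))) / np.mean(w))


def spectral_entropy(nbs: NormalizedBandSpectrum) -> float:
    """Normalized Shannon entropy of the band power distribution."""
    if nbs.N < 2:
        raise ValueError("entropy needs at least 2 frequency bins")
    w = nbs.Wn[nbs.Wn > 0]  # 0 * ln 0 := 0
    return float(-np.sum(w * np.log(w)) / np.log(nbs.N))


def renyi_entropy(nbs: NormalizedBandSpectrum, alpha: float = 0.1) -> float:
    """Normalized Renyi entropy of order ``alpha`` (alpha >= 0, != 1).

    Converges to the Shannon spectral entropy as alpha -> 1; the study
    default alpha = 0.1 weights the many small bins heavily, making the
    index sensitive to subtle redistribution of power.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 1:
        raise ValueError("alpha = 1 is the Shannon limit; use spectral_entropy")
    if nbs.N < 2:
        raise ValueError("entropy needs at least 2 frequency bins")
    w = nbs.Wn[nbs.Wn > 0]
    return float(np.log(np.sum(w**alpha)) / ((1.0 - alpha) * np.log(nbs.N)))


def c0_complexity(nbs: NormalizedBandSpectrum) -> float:
    """C0 complexity: share of band power in the irregular part.

    Bins whose normalized power exceeds twice the band mean are regarded
    as the regular (harmonic) part and removed; C0 is the power ratio of
    what remains to the whole, i.e. ``sum(Wirr)`` for a unit-power band.
    """
    return float(nbs.Wirr.sum() / nbs.Wn.sum())


# ---------------------------------------------------------------------------
# composition


def extract_all(
    fwave: FWaveSignal,
    alpha: float = 0.1,
    df_band: tuple[float, float] = DF_BAND,
) -> SpectralFeatures:
    """Compute the full spectral feature vector of one f-wave segment."""
    psd = welch_psd(fwave)
    f0, Wf0 = find_dominant(psd, df_band)
    f1, Wf1 = find_first_harmonic(psd, f0)
    g = gamma(Wf0, Wf1)
    O = organization_index(psd, f0)
    bands = band_limits(f0)
    per_band: dict[str, float] = {}
    for band in bands:
        nbs = normalize_band(psd, band)
        per_band[f"F_{band.label}"] = wiener_flatness(nbs)
        per_band[f"S_{band.label}"] = spectral_entropy(nbs)
        per_band[f"R_{band.label}"] = renyi_entropy(nbs, alpha)
        per_band[f"C0_{band.label}"] = c0_complexity(nbs)
    return SpectralFeatures(
        f0=f0, Wf0=Wf0, f1=f1, Wf1=Wf1, gamma=g, O=O, alpha=alpha, **per_band
    )


def average_per_patient(
    per_segment: Sequence[SpectralFeatures], patient_id: str, label: str
) -> dict[str, object]:
    """Average a patient's per-segment features into one table row."""
    if not per_segment:
        raise ValueError("a patient needs at least one analysed segment")
    row: dict[str, object] = {"patient_id": patient_id, "label": label}
    for name in FEATURE_COLUMNS:
        row[name] = float(np.mean([getattr(f, name) for f in per_segment]))
    return row


def cohort_table(rows: Iterable[dict[str, object]]) -> pd.DataFrame:
    """Assemble per-patient rows into a cohort feature table."""
    df = pd.DataFrame(list(rows))
    if df.empty:
        raise ValueError("cohort table is empty")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in cohort table")
    return df
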