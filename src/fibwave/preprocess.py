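"""ECG conditioning ahead of f-wave analysis.

Three disturbances dominate resting single-lead recordings: baseline
wander, powerline interference and high-frequency noise.  They are removed
in that order by (i) subtracting a zero-phase low-pass (0.8 Hz) baseline
estimate, (ii) a stationary-wavelet-transform denoiser that soft-thresholds
the detail levels whose dyadic bands contain the mains frequency and its
harmonics, and (iii) a zero-phase 70 Hz low-pass.  All filters are applied
forward/backward, so the chain is strictly zero-phase and preserves sample
count and sampling rate.

Recordings of variable duration are then cut into consecutive 6-s analysis
segments, keeping at most five per patient.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from .signals import EcgSegment

__all__ = [
    "remove_baseline",
    "remove_powerline",
    "lowpass_hf",
    "preprocess",
    "segment_recording",
]

#: minimum segment duration for stable forward/backward IIR filtering, s
_MIN_FILTER_DURATION = 3.0


def _check_length(segment: EcgSegment, minimum: float = _MIN_FILTER_DURATION) -> None:
    if segment.duration < minimum:
        raise ValueError(
            f"segment of {segment.duration:.2f} s is shorter than the "
            f"{minimum:.1f} s minimum required for zero-phase filtering"
        )


def _filtfilt_padded(sos: np.ndarray, x: np.ndarray, fs: float,
                     pad_s: float = 3.0) -> np.ndarray:
    """Forward/backward filtering with generous reflect padding.

    The default filtfilt padding is too short for a sub-hertz cut-off; a
    few seconds of odd-reflection padding keeps the filter transient out
    of the analysed samples.
    """
    n_pad = min(int(round(pad_s * fs)), x.size - 1)
    xp = np.pad(x, n_pad, mode="reflect", reflect_type="odd")
    y = sps.sosfiltfilt(sos, xp)
    return y[n_pad : n_pad + x.size]


def remove_baseline(segment: EcgSegment, cutoff: float = 0.8) -> EcgSegment:
    """Subtract the baseline-wander estimate from a segment.

    The wander is estimated with a 4th-order Butterworth low-pass at
    ``cutoff`` Hz applied forward/backward (zero phase) and subtracted,
    leaving the cardiac content untouched down to ~1 Hz.
    """
    _check_length(segment)
    sos = sps.butter(4, cutoff, btype="low", fs=segment.fs, output="sos")
    wander = _filtfilt_padded(sos, segment.samples, segment.fs)
    return segment.with_samples(segment.samples - wander)


def _mains_levels(fs: float, mains_freq: float, depth: int) -> list[int]:
    """SWT decomposition levels whose detail band holds a mains harmonic.

    Level ``j`` of an SWT spans roughly ``[fs / 2**(j+1), fs / 2**j]`` Hz.
    """
    levels = []
    for j in range(1, depth + 1):
        lo, hi = fs / 2 ** (j + 1), fs / 2**j
        harmonics = np.arange(mains_freq, fs / 2, mains_freq)
        if np.any((harmonics >= lo) & (harmonics < hi)):
            levels.append(j)
    return levels


def remove_powerline(
    segment: EcgSegment, mains_freq: float = 50.0, wavelet: str = "db4"
) -> EcgSegment:
    """Suppress mains interference with an SWT denoiser.

    The signal is decomposed with an undecimated (stationary) wavelet
    transform deep enough that the mains frequency falls inside one detail
    level.  In every detail level whose band contains the mains frequency
    or one of its harmonics, the coefficients are soft-thresholded with the
    universal threshold ``sigma * sqrt(2 ln n)`` where ``sigma`` is the
    median-based robust scale of that level.  A narrowband tone saturates
    its level's coefficients, which the threshold removes entirely, while
    the broadband-poor f-wave content (3-25 Hz) lives in the approximation
    and remains untouched.
    """
    fs = segment.fs
    if mains_freq >= fs / 2:
        raise ValueError("mains frequency must be below the Nyquist frequency")
    # depth such that the mains fundamental sits inside one detail band
    depth = 1
    while not (fs / 2 ** (depth + 1) <= mains_freq):
        depth += 1
    target = set(_mains_levels(fs, mains_freq, depth))

    x = segment.samples
    n = x.size
    pad = (-n) % (2**depth)
    xp = np.pad(x, (0, pad), mode="symmetric") if pad else x
    coeffs = pywt.swt(xp, wavelet, level=depth)
    cleaned = []
    for i, (ca, cd) in enumerate(coeffs):
        level = depth - i  # pywt orders coefficients from the deepest level
        if level in target:
            sigma = np.median(np.abs(cd)) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(cd.size))
            cd = np.sign(cd) * np.maximum(np.abs(cd) - thr, 0.0)
        cleaned.append((ca, cd))
    y = pywt.iswt(cleaned, wavelet)[:n]
    return segment.with_samples(y)


def lowpass_hf(segment: EcgSegment, cutoff: float = 70.0) -> EcgSegment:
    """Zero-phase 6th-order Butterworth low-pass for high-frequency noise."""
    if segment.fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {segment.fs} Hz too low for a {cutoff} Hz cut-off"
        )
    _check_length(segment)
    sos = sps.butter(6, cutoff, btype="low", fs=segment.fs, output="sos")
    return segment.with_samples(_filtfilt_padded(sos, segment.samples, segment.fs))


def preprocess(segment: EcgSegment, mains_freq: float = 50.0) -> EcgSegment:
    """Full conditioning chain: baseline, then mains, then 70 Hz low-pass."""
    out = remove_baseline(segment)
    out = remove_powerline(out, mains_freq=mains_freq)
    return lowpass_hf(out)


def segment_recording(
    record: EcgSegment, seg_len: float = 6.0, max_segments: int = 5
) -> list[EcgSegment]:
    """Cut a recording into consecutive non-overlapping analysis segments.

    Segments are anchored at the start of the record; the trailing
    remainder shorter than ``seg_len`` is discarded, and at most
    ``max_segments`` segments are returned.
    """
    n_per = int(round(seg_len * record.fs))
    if len(record) < n_per:
        raise ValueError(
            f"record of {record.duration:.2f} s is shorter than one "
            f"{seg_len:.0f}-s segment"
        )
    n_full = min(len(record) // n_per, max_segments)
    return [
        EcgSegment(
            samples=record.samples[k * n_per : (k + 1) * n_per],
            fs=record.fs,
            t0=record.t0 + k * n_per / record.fs,
            lead=record.lead,
        )
        for k in range(n_full)
    ]
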