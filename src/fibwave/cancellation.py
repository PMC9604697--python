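"""Ventricular cancellation: extracting f-waves from the conditioned ECG.

The atrial signal is obscured by the much larger QRST complexes.  They are
removed by adaptive singular value cancellation (ASVC): R-peak-aligned
beats form a matrix whose dominant left singular vector is the cancellation
template; the template is then subtracted from each beat scaled by a
per-beat least-squares amplitude, and a linear edge-correction ramp keeps
the residual continuous at the beat-window boundaries so that no
subtraction step leaks spectral energy into the f-wave band.  Samples
outside beat windows are never touched.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .signals import BeatAnnotations, EcgSegment, FWaveSignal

__all__ = ["detect_r_peaks", "build_qrst_template", "cancel_qrst"]

#: default cancellation window around the R peak, seconds (pre, post)
DEFAULT_BEAT_WINDOW = (0.25, 0.45)

#: ventricular refractory period, seconds
REFRACTORY = 0.2


def detect_r_peaks(segment: EcgSegment) -> BeatAnnotations:
    """Locate R peaks with an energy-envelope detector.

    The segment is band-passed to 5-25 Hz, squared and integrated over a
    150 ms moving window.  A crest-factor gate (envelope max over envelope
    mean) separates beat trains, whose envelope is spiky, from beat-free
    f-waves, whose envelope is nearly flat; when beats are present, peaks
    above 30% of the envelope maximum separated by a 200 ms refractory
    period are taken as beats and refined to the local absolute maximum of
    the band-passed signal.  Gate and threshold are both relative, so
    detection indices are invariant to amplitude scaling.
    """
    fs = segment.fs
    sos = sps.butter(3, [5.0, 25.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, segment.samples)
    env = np.convolve(bp**2, np.ones(int(round(0.15 * fs))) / (0.15 * fs), "same")

    env_mean = env.mean()
    if env_mean <= 0 or env.max() / env_mean < 3.0:
        return BeatAnnotations(r_peaks=np.array([], dtype=int), fs=fs)
    thr = 0.3 * env.max()
    distance = max(int(round(REFRACTORY * fs)), 1)
    peaks, _ = sps.find_peaks(env, height=thr, distance=distance)

    # refine to the local |bp| maximum within +-50 ms
    half = int(round(0.05 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(bp))
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = sorted(set(refined))
    # enforce the refractory period after refinement
    kept: list[int] = []
    for idx in refined:
        if not kept or idx - kept[-1] >= distance:
            kept.append(idx)
    return BeatAnnotations(r_peaks=np.array(kept, dtype=int), fs=fs)


def _beat_matrix(
    samples: np.ndarray,
    beats: BeatAnnotations,
    pre_n: int,
    post_n: int,
) -> tuple[np.ndarray, list[int]]:
    """Stack beats whose full window lies inside the segment (columns)."""
    cols, used = [], []
    for r in beats.r_peaks:
        lo, hi = r - pre_n, r + post_n + 1
        if lo >= 0 and hi <= samples.size:
            cols.append(samples[lo:hi])
            used.append(int(r))
    if not cols:
        return np.empty((pre_n + post_n + 1, 0)), []
    return np.column_stack(cols), used


def build_qrst_template(
    segment: EcgSegment,
    beats: BeatAnnotations,
    window: tuple[float, float] = DEFAULT_BEAT_WINDOW,
) -> np.ndarray:
    """SVD cancellation template from R-aligned beats.

    The template is the dominant left singular vector of the beat matrix,
    scaled by the singular-value-weighted mean beat amplitude, so it
    carries the morphology shared by all beats while averaging out the
    uncorrelated atrial activity and noise.
    """
    fs = segment.fs
    pre_n, post_n = int(round(window[0] * fs)), int(round(window[1] * fs))
    X, used = _beat_matrix(segment.samples, beats, pre_n, post_n)
    if X.shape[1] < 2:
        raise ValueError(
            f"need >= 2 complete beats inside the segment to build a "
            f"template, found {X.shape[1]}; skip this segment"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    template = U[:, 0] * (s[0] * Vt[0].mean())
    # orient the template like the mean beat
    if np.dot(template, X.mean(axis=1)) < 0:
        template = -template
    return template


def cancel_qrst(
    segment: EcgSegment,
    beats: BeatAnnotations,
    window: tuple[float, float] = DEFAULT_BEAT_WINDOW,
) -> FWaveSignal:
    """Subtract the amplitude-adapted QRST template from every beat.

    Each beat window receives the template scaled by its least-squares
    amplitude coefficient.  Windows are truncated at the segment edges;
    when neighbouring beats are closer than the nominal window, the
    overlap is split in proportion to the pre/post extents so consecutive
    windows tile the RR interval without leaving an uncancelled T-wave
    tail.  A linear ramp interpolating the residual's boundary mismatches
    is then subtracted so the residual joins the surrounding signal
    without step discontinuities.
    """
    if len(beats) == 0:
        warnings.warn("no beats annotated; returning the input unchanged")
        return FWaveSignal(
            samples=segment.samples.copy(), fs=segment.fs, source_segment=segment
        )
    fs = segment.fs
    pre_n, post_n = int(round(window[0] * fs)), int(round(window[1] * fs))
    try:
        template = build_qrst_template(segment, beats, window)
    except ValueError:
        warnings.warn("fewer than 2 complete beats; returning input unchanged")
        return FWaveSignal(
            samples=segment.samples.copy(), fs=segment.fs, source_segment=segment
        )

    y = segment.samples.copy()
    n = y.size
    r = beats.r_peaks
    frac_post = post_n / (pre_n + post_n)
    for i, ri in enumerate(r):
        pre_i = min(pre_n, ri)
        post_i = min(post_n, n - 1 - ri)
        if i > 0 and ri - r[i - 1] < pre_n + post_n:
            pre_i = min(pre_i, ri - r[i - 1] - int(round((ri - r[i - 1]) * frac_post)) - 1)
            pre_i = max(pre_i, 0)
        if i < len(r) - 1 and r[i + 1] - ri < pre_n + post_n:
            post_i = min(post_i, int(round((r[i + 1] - ri) * frac_post)))
        lo, hi = ri - pre_i, ri + post_i + 1
        tmpl = template[pre_n - pre_i : pre_n + post_i + 1]
        denom = float(np.dot(tmpl, tmpl))
        if denom == 0.0 or hi - lo < 3:
            continue
        a = float(np.dot(y[lo:hi], tmpl)) / denom
        resid = y[lo:hi] - a * tmpl
        # linear edge correction: tie the residual to its neighbours
        d0 = resid[0] - y[lo - 1] if lo > 0 else 0.0
        d1 = resid[-1] - y[hi] if hi < n else 0.0
        resid -= np.linspace(d0, d1, resid.size)
        y[lo:hi] = resid
    return FWaveSignal(samples=y, fs=fs, source_segment=segment)
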