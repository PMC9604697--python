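"""Core signal containers and plain-text I/O.

Single-lead ECG excerpts are represented as uniformly sampled voltage
traces in millivolts.  Files are exchanged as two-column CSV
(time in seconds, voltage in mV) so that every artefact of a run is
human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EcgSegment",
    "FWaveSignal",
    "BeatAnnotations",
    "read_signal_csv",
    "write_signal_csv",
]


@dataclass(frozen=True)
class EcgSegment:
    """A uniformly sampled single-lead voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in mV.
    fs : float
        Sampling rate in Hz (nominally 977 Hz for the target recordings).
    t0 : float
        Start offset of the segment within its parent recording, seconds.
    lead : str
        Lead label; V1 is the conventional lead for atrial activity.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    lead: str = "V1"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgSegment":
        """Return a copy carrying new samples but identical metadata."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class FWaveSignal:
    """Atrial residual of one segment after ventricular cancellation."""

    samples: np.ndarray
    fs: float
    source_segment: EcgSegment | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise ValueError("f-wave samples contain non-finite values")
        if self.source_segment is not None and len(samples) != len(
            self.source_segment
        ):
            raise ValueError("f-wave length must match its source segment")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class BeatAnnotations:
    """R-peak sample indices of one segment (strictly increasing)."""

    r_peaks: np.ndarray
    fs: float

    #: physiologic lower bound on the RR interval, seconds
    min_rr: float = field(default=0.2, repr=False)

    def __post_init__(self) -> None:
        peaks = np.asarray(self.r_peaks, dtype=int)
        object.__setattr__(self, "r_peaks", peaks)
        if peaks.size and np.any(np.diff(peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        if peaks.size and peaks[0] < 0:
            raise ValueError("r_peaks must be non-negative")
        if peaks.size >= 2 and np.min(np.diff(peaks)) < self.min_rr * self.fs:
            raise ValueError(
                f"RR interval below {self.min_rr * 1e3:.0f} ms refractory bound"
            )

    def __len__(self) -> int:
        return self.r_peaks.size

    @property
    def times(self) -> np.ndarray:
        return self.r_peaks / self.fs


def write_signal_csv(segment: EcgSegment, path: str | Path) -> Path:
    """Write a segment as two-column CSV (time_s, voltage_mV)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": segment.time, "voltage_mV": segment.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_signal_csv(
    path: str | Path, fs: float | None = None, lead: str = "V1"
) -> EcgSegment:
    """Read a two-column CSV (time, mV) back into an :class:`EcgSegment`.

    The sampling rate is inferred from the median time step unless given.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, voltage)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        dt = np.median(np.diff(t))
        if not np.isfinite(dt) or dt <= 0:
            raise ValueError(f"{path}: cannot infer sampling rate")
        fs = 1.0 / dt
    return EcgSegment(samples=v, fs=float(fs), t0=float(t[0]), lead=lead)
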