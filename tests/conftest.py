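"""Shared fixtures: small synthetic signals and cohorts built at test time."""

import numpy as np
import pytest

from fibwave.signals import EcgSegment
from fibwave.synth import FWaveModelParams, VentricularModelParams, generate_ecg

FS = 977.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


def make_tone(freq: float, duration: float = 6.0, amp: float = 1.0,
              fs: float = FS, phase: float = 0.0) -> EcgSegment:
    t = np.arange(int(round(duration * fs))) / fs
    return EcgSegment(samples=amp * np.sin(2 * np.pi * freq * t + phase), fs=fs)


@pytest.fixture
def tone6() -> EcgSegment:
    """A clean 6 Hz unit sinusoid, 6 s."""
    return make_tone(6.0)


@pytest.fixture
def af_ecg():
    """A default AF-like composite ECG (30 s) with ground truth."""
    fparams = FWaveModelParams(f0_true=6.0, harmonic_log_decay=2.0, n_harmonics=3)
    vparams = VentricularModelParams()
    return generate_ecg(fparams, vparams, duration=30.0, seed=11)
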