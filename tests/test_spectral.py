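"""Spectral-feature contracts, hand-computed oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibwave.signals import FWaveSignal
from fibwave.spectral import (
    BandDefinition,
    NormalizedBandSpectrum,
    PowerSpectrum,
    average_per_patient,
    band_limits,
    c0_complexity,
    extract_all,
    find_dominant,
    find_first_harmonic,
    gamma,
    normalize_band,
    organization_index,
    renyi_entropy,
    spectral_entropy,
    welch_psd,
    wiener_flatness,
)

from .conftest import FS, make_tone


def fwave_signal(samples: np.ndarray, fs: float = FS) -> FWaveSignal:
    return FWaveSignal(samples=samples, fs=fs)


def nbs_from(values) -> NormalizedBandSpectrum:
    w = np.asarray(values, dtype=float)
    w = w / w.sum()
    return NormalizedBandSpectrum(freqs=np.arange(w.size) * 0.1 + 3.0, Wn=w)


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain-loop evaluations of the formulas)


def oracle_flatness(w):
    gm = math.exp(sum(math.log(v) for v in w) / len(w)) if all(v > 0 for v in w) else 0.0
    am = sum(w) / len(w)
    return gm / am


def oracle_shannon(wn):
    total = -sum(v * math.log(v) for v in wn if v > 0)
    return total / math.log(len(wn))


def oracle_renyi(wn, a):
    return math.log(sum(v**a for v in wn if v > 0)) / ((1 - a) * math.log(len(wn)))


def oracle_c0(wn):
    thr = 2.0 / len(wn) * sum(wn)
    return sum(v for v in wn if v <= thr) / sum(wn)


# ---------------------------------------------------------------------------


class TestWelchPsd:
    def test_single_tone_peak_location(self, tone6):
        psd = welch_psd(fwave_signal(tone6.samples))
        assert psd.freqs[np.argmax(psd.W)] == pytest.approx(6.0, abs=0.05)
        step = np.diff(psd.freqs)
        np.testing.assert_allclose(step, 0.1, atol=1e-9)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(0)
        psd = welch_psd(fwave_signal(rng.normal(size=int(6 * FS))))
        low = psd.W[(psd.freqs >= 3) & (psd.freqs <= 25)].mean()
        high = psd.W[(psd.freqs >= 30) & (psd.freqs <= 60)].mean()
        assert 0.8 <= low / high <= 1.25

    def test_total_power_consistent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=int(6 * FS)) + make_tone(7.0).samples
        psd = welch_psd(fwave_signal(x))
        total = np.sum(psd.W) * 0.1
        assert total == pytest.approx(np.var(x), rel=0.2)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="Welch window"):
            welch_psd(fwave_signal(np.zeros(1000)))


class TestPeakLocation:
    def test_single_tone(self, tone6):
        psd = welch_psd(fwave_signal(tone6.samples))
        f0, wf0 = find_dominant(psd)
        assert f0 == pytest.approx(6.0, abs=0.05)
        assert wf0 == psd.W.max()

    def test_larger_amplitude_wins(self):
        x = make_tone(5.0, amp=1.0).samples + make_tone(7.3, amp=1.2).samples
        f0, _ = find_dominant(welch_psd(fwave_signal(x)))
        assert f0 == pytest.approx(7.3, abs=0.05)

    def test_tie_breaks_low(self):
        freqs = np.arange(0, 71, 0.1)
        W = np.ones_like(freqs)
        psd = PowerSpectrum(freqs=freqs, W=W, fs=FS)
        f0, _ = find_dominant(psd)
        assert f0 == pytest.approx(3.0)

    def test_first_harmonic_window(self):
        x = make_tone(6.0).samples + 0.5 * make_tone(12.3).samples
        psd = welch_psd(fwave_signal(x))
        f1, _ = find_first_harmonic(psd, 6.0)
        assert f1 == pytest.approx(12.3, abs=0.05)

    def test_harmonic_always_inside_window(self):
        rng = np.random.default_rng(2)
        x = make_tone(6.0).samples + 0.01 * rng.normal(size=int(6 * FS))
        f1, _ = find_first_harmonic(welch_psd(fwave_signal(x)), 6.0)
        assert 11.5 - 1e-6 <= f1 <= 12.5 + 1e-6

    def test_leakage_far_below_peak(self, tone6):
        psd = welch_psd(fwave_signal(tone6.samples))
        _, wf0 = find_dominant(psd)
        _, wf1 = find_first_harmonic(psd, 6.0)
        assert wf1 / wf0 < 0.05


class TestGamma:
    def test_closed_forms(self):
        assert gamma(1.0, 1.0) == 0.0
        assert gamma(np.e**2, 1.0) == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gamma(0.0, 1.0)

    def test_simulator_ground_truth(self):
        from fibwave.synth import FWaveModelParams, generate_fwave

        p = FWaveModelParams(f0_true=6.0, harmonic_log_decay=2.8, n_harmonics=2)
        seg = generate_fwave(p, 6.0, FS, seed=1)
        feats = extract_all(fwave_signal(seg.samples))
        assert feats.gamma == pytest.approx(2.8, abs=0.1)


class TestOrganizationIndex:
    def test_pure_tone_concentrated(self, tone6):
        psd = welch_psd(fwave_signal(tone6.samples))
        assert organization_index(psd, 6.0) >= 0.95

    def test_white_noise_window_fraction(self):
        # three 1 Hz windows of a 22 Hz band ~ 3/22
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            psd = welch_psd(fwave_signal(rng.normal(size=int(6 * FS))))
            f0, _ = find_dominant(psd)
            vals.append(organization_index(psd, f0))
        assert np.mean(vals) == pytest.approx(3 / 22, abs=0.05)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            psd = welch_psd(fwave_signal(rng.normal(size=int(6 * FS))))
            f0, _ = find_dominant(psd)
            assert 0.0 <= organization_index(psd, f0) <= 1.0


class TestBandLimits:
    @pytest.mark.parametrize("f0,cut", [(6.0, 9.0), (4.0, 6.0)])
    def test_cutoff_at_three_halves(self, f0, cut):
        lf, hf, tf = band_limits(f0)
        assert (lf.fl, lf.fu) == (3.0, cut)
        assert (hf.fl, hf.fu) == (cut, 25.0)
        assert hf.open_lower

    @pytest.mark.parametrize("f0", [3.0, 5.7, 8.2, 12.0])
    def test_lf_hf_partition_tf(self, f0):
        lf, hf, tf = band_limits(f0)
        freqs = np.arange(0, 71, 0.1)
        psd = PowerSpectrum(freqs=freqs, W=np.ones_like(freqs), fs=FS)
        m_lf = psd.band_mask(lf.fl, lf.fu, lf.open_lower)
        m_hf = psd.band_mask(hf.fl, hf.fu, hf.open_lower)
        m_tf = psd.band_mask(tf.fl, tf.fu, tf.open_lower)
        assert not np.any(m_lf & m_hf)
        np.testing.assert_array_equal(m_lf | m_hf, m_tf)


class TestNormalizeBand:
    def test_uniform(self):
        nbs = nbs_from([1.0] * 10)
        assert nbs.T == pytest.approx(0.2)
        np.testing.assert_allclose(nbs.Wirr, nbs.Wn)

    def test_single_spike_removed(self):
        nbs = nbs_from([1.0, 0.0, 0.0])
        assert nbs.Wirr[0] == 0.0

    def test_hand_example(self):
        nbs = nbs_from([0.7, 0.2, 0.1])
        assert nbs.T == pytest.approx(2 / 3)
        np.testing.assert_allclose(nbs.Wirr, [0.0, 0.2, 0.1])

    def test_zero_band_power_rejected(self):
        freqs = np.arange(0, 71, 0.1)
        psd = PowerSpectrum(freqs=freqs, W=np.zeros_like(freqs), fs=FS)
        with pytest.raises(ValueError, match="zero power"):
            normalize_band(psd, BandDefinition(3.0, 25.0, "TF"))


class TestDistributionMeasures:
    def test_flatness_cases(self):
        assert wiener_flatness(nbs_from([1.0] * 5)) == pytest.approx(1.0)
        assert wiener_flatness(nbs_from([1.0, 0.0, 1.0])) == 0.0
        assert wiener_flatness(nbs_from([4.0, 1.0])) == pytest.approx(0.8)

    def test_shannon_cases(self):
        assert spectral_entropy(nbs_from([1.0] * 8)) == pytest.approx(1.0)
        assert spectral_entropy(nbs_from([1.0, 0.0, 0.0])) == 0.0
        assert spectral_entropy(nbs_from([0.5, 0.25, 0.25])) == pytest.approx(
            0.946, abs=0.001
        )

    def test_renyi_cases(self):
        assert renyi_entropy(nbs_from([1.0] * 8), 0.1) == pytest.approx(1.0)
        assert renyi_entropy(nbs_from([1.0] * 8), 2.0) == pytest.approx(1.0)
        assert renyi_entropy(nbs_from([0.5, 0.25, 0.25]), 0.1) == pytest.approx(
            0.995, abs=0.001
        )
        with pytest.raises(ValueError, match="Shannon"):
            renyi_entropy(nbs_from([1.0, 2.0]), 1.0)

    def test_renyi_shannon_limit(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            nbs = nbs_from(rng.uniform(0.01, 1.0, size=50))
            s = spectral_entropy(nbs)
            for a in (1 - 1e-4, 1 + 1e-4):
                assert abs(renyi_entropy(nbs, a) - s) <= 1e-3

    def test_c0_cases(self):
        assert c0_complexity(nbs_from([1.0] * 6)) == pytest.approx(1.0)
        assert c0_complexity(nbs_from([1.0, 0.0, 0.0])) == 0.0
        assert c0_complexity(nbs_from([0.7, 0.2, 0.1])) == pytest.approx(0.3)

    def test_oracle_equivalence_on_random_spectra(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = rng.integers(3, 120)
            w = rng.uniform(1e-6, 1.0, size=n)
            nbs = nbs_from(w)
            wn = list(nbs.Wn)
            assert wiener_flatness(nbs) == pytest.approx(
                oracle_flatness(wn), abs=1e-10
            )
            assert spectral_entropy(nbs) == pytest.approx(
                oracle_shannon(wn), abs=1e-10
            )
            assert renyi_entropy(nbs, 0.1) == pytest.approx(
                oracle_renyi(wn, 0.1), abs=1e-10
            )
            assert c0_complexity(nbs) == pytest.approx(oracle_c0(wn), abs=1e-10)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(1e-9, 1.0), min_size=3, max_size=80),
        st.floats(0.0, 0.99),
        st.floats(1.01, 5.0),
    )
    def test_bounds_and_renyi_monotonicity(self, values, a_low, a_high):
        nbs = nbs_from(values)
        f, s, c0 = wiener_flatness(nbs), spectral_entropy(nbs), c0_complexity(nbs)
        r_low, r_high = renyi_entropy(nbs, a_low), renyi_entropy(nbs, a_high)
        for v in (f, s, c0, r_low, r_high):
            assert -1e-12 <= v <= 1 + 1e-9
        assert r_low >= r_high - 1e-9  # Renyi entropy decreases in alpha


class TestExtractAll:
    def test_noise_free_two_harmonic(self):
        from fibwave.synth import FWaveModelParams, generate_fwave

        p = FWaveModelParams(f0_true=6.0, harmonic_log_decay=2.0, n_harmonics=2)
        seg = generate_fwave(p, 6.0, FS, seed=6)
        feats = extract_all(fwave_signal(seg.samples))
        assert feats.f0 == pytest.approx(6.0, abs=0.05)
        assert feats.gamma == pytest.approx(2.0, abs=0.1)

    def test_white_noise_is_flat_and_complex(self):
        # flat-spectrum expectations at the Welch settings in use: the
        # chi-square scatter of the averaged periodogram caps the flatness
        # of even a perfectly white input near 0.7 (C0 slightly below it)
        vals = {"F_TF": [], "S_TF": [], "R_TF": [], "C0_TF": []}
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            feats = extract_all(fwave_signal(rng.normal(size=int(6 * FS))))
            for k in vals:
                vals[k].append(getattr(feats, k))
        for k in ("F_TF", "S_TF", "R_TF"):
            assert np.mean(vals[k]) >= 0.7, k
        assert np.mean(vals["C0_TF"]) >= 0.6

    def test_tone_less_complex_than_noise(self):
        rng = np.random.default_rng(7)
        noise = rng.normal(size=int(6 * FS))
        tone = make_tone(6.0).samples + 0.05 * noise
        c0_tone = extract_all(fwave_signal(tone)).C0_TF
        c0_noise = extract_all(fwave_signal(noise)).C0_TF
        assert c0_tone < c0_noise

    @pytest.mark.parametrize("f0_true", np.arange(4.0, 9.01, 0.5).tolist())
    def test_dominant_frequency_recovery_grid(self, f0_true):
        from fibwave.synth import FWaveModelParams, generate_fwave

        p = FWaveModelParams(f0_true=f0_true, harmonic_log_decay=2.0, n_harmonics=2)
        seg = generate_fwave(p, 6.0, FS, seed=8)
        feats = extract_all(fwave_signal(seg.samples))
        assert abs(feats.f0 - f0_true) <= 0.05

    def test_scale_invariance(self):
        from fibwave.synth import FWaveModelParams, generate_fwave

        p = FWaveModelParams(noise_sd=0.01)
        seg = generate_fwave(p, 6.0, FS, seed=9)
        a = extract_all(fwave_signal(seg.samples))
        b = extract_all(fwave_signal(7.3 * seg.samples))
        for name in ("f0", "f1", "gamma", "O", "F_TF", "S_LF", "R_HF", "C0_TF"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-9)
        assert b.Wf0 == pytest.approx(7.3**2 * a.Wf0, rel=1e-6)

    def test_feature_invariants(self):
        rng = np.random.default_rng(10)
        feats = extract_all(fwave_signal(rng.normal(size=int(6 * FS))))
        assert 3.0 <= feats.f0 <= 12.0
        assert 2 * feats.f0 - 0.5 - 1e-6 <= feats.f1 <= 2 * feats.f0 + 0.5 + 1e-6
        assert 0.0 <= feats.O <= 1.0
        for band in ("LF", "HF", "TF"):
            for meas in ("F", "S", "R", "C0"):
                assert 0.0 <= getattr(feats, f"{meas}_{band}") <= 1.0


class TestAveragePerPatient:
    def _feats(self, g):
        from dataclasses import replace

        base = extract_all(fwave_signal(make_tone(6.0).samples + 0.01))
        return replace(base, gamma=g)

    def test_single_segment_identity(self):
        f = self._feats(2.0)
        row = average_per_patient([f], "p1", "SR")
        assert row["gamma"] == 2.0
        assert row["patient_id"] == "p1"

    def test_mean_of_two(self):
        row = average_per_patient([self._feats(2.0), self._feats(3.0)], "p", "recur")
        assert row["gamma"] == pytest.approx(2.5)

    def test_mean_idempotent(self):
        f = self._feats(2.2)
        row = average_per_patient([f] * 5, "p", "SR")
        assert row["gamma"] == pytest.approx(2.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_per_patient([], "p", "SR")
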