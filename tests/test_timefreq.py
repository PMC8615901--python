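"""Morlet amplitude analysis: calibration, trimming, baseline, band scoring."""

import numpy as np
import pytest

from munet.epochs import EpochSet
from munet.timefreq import (
    TimeFrequencyError,
    band_cluster_mean,
    band_indices,
    baseline_subtract,
    morlet_coefficients,
    morlet_tfr,
    trim_edges,
)


def _sine_epochs(freq=7.0, amp=1.0, n_trials=1, n_channels=1, fs=500.0, n=1200, phase=0.0):
    t = np.arange(n) / fs
    sig = amp * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(sig, (n_trials, n_channels, 1))
    return EpochSet(data=data, fs=fs)


class TestMorlet:
    def test_peak_frequency_and_linearity(self):
        r1 = morlet_tfr(_sine_epochs(amp=1.0))
        r2 = morlet_tfr(_sine_epochs(amp=2.0))
        mid = slice(400, 800)
        prof1 = r1.amplitude[0, :, mid].mean(axis=-1)
        assert r1.freqs[np.argmax(prof1)] == 7.0
        assert np.allclose(2 * r1.amplitude[:, :, mid], r2.amplitude[:, :, mid], rtol=1e-6)

    def test_amplitude_in_signal_units(self):
        """A 2.5 µV sinusoid reads 2.5 µV at its own frequency bin."""
        r = morlet_tfr(_sine_epochs(freq=7.0, amp=2.5))
        k = int(np.flatnonzero(r.freqs == 7.0)[0])
        assert r.amplitude[0, k, 400:800].mean() == pytest.approx(2.5, rel=1e-3)

    def test_constant_signal_rejected(self):
        es = EpochSet(data=np.full((1, 1, 1200), 30.0))
        r = morlet_tfr(es)
        assert r.amplitude[0, :, 400:800].max() < 1e-3 * 30.0

    def test_white_noise_flat_in_time_after_trim(self, rng):
        es = EpochSet(data=rng.standard_normal((200, 1, 1200)))
        r = trim_edges(morlet_tfr(es))
        course = r.amplitude[0].mean(axis=0)  # frequency-averaged time course
        assert (course.max() - course.min()) / course.mean() < 0.10

    def test_nyquist_guard(self, rng):
        es = EpochSet(data=rng.standard_normal((1, 1, 1200)))
        with pytest.raises(TimeFrequencyError):
            morlet_tfr(es, f_max=300.0)

    def test_trial_average_of_modulus_dominates(self, rng):
        """Jensen: averaging moduli >= modulus of the averaged coefficients."""
        data = rng.standard_normal((20, 1, 1200))
        coefs = morlet_coefficients(data, 500.0, np.array([7.0]))
        avg_of_mod = np.abs(coefs).mean(axis=0)
        mod_of_avg = np.abs(coefs.mean(axis=0))
        assert np.all(avg_of_mod >= mod_of_avg - 1e-12)
        assert avg_of_mod.mean() > 1.5 * mod_of_avg.mean()

    def test_matches_mne_up_to_scale(self):
        """Cross-check against MNE's Morlet TFR: same shape up to one gain."""
        from mne.time_frequency import tfr_array_morlet

        es = _sine_epochs(freq=7.0, amp=1.5, n_trials=2)
        freqs = np.arange(5.0, 10.0)
        ours = np.abs(morlet_coefficients(es.data, es.fs, freqs))
        theirs = np.abs(
            tfr_array_morlet(
                es.data, es.fs, freqs, n_cycles=5.0, output="complex", verbose="error"
            )
        )[:, :, 0 : len(freqs)]
        mid = slice(300, 900)
        ratio = theirs[..., mid] / ours[..., mid]
        # one global gain per frequency, constant over time and trials
        for k in range(len(freqs)):
            r = ratio[:, 0, k]
            assert r.std() / r.mean() < 0.01


class TestTrim:
    def test_trim_sample_count(self):
        r = morlet_tfr(_sine_epochs())
        out = trim_edges(r, 400.0)
        assert out.times_ms.size == 800
        assert out.times_ms[0] == pytest.approx(-600.0)
        assert out.times_ms[-1] <= 1000.0
        assert out.trimmed

    def test_double_trim_errors(self):
        out = trim_edges(morlet_tfr(_sine_epochs()))
        with pytest.raises(TimeFrequencyError):
            trim_edges(out)

    def test_zero_trim_identity(self):
        r = morlet_tfr(_sine_epochs())
        out = trim_edges(r, 0.0)
        assert np.array_equal(out.amplitude, r.amplitude)

    def test_over_trim_errors(self):
        with pytest.raises(TimeFrequencyError):
            trim_edges(morlet_tfr(_sine_epochs()), 1300.0)


class TestBaseline:
    def test_baseline_window_mean_zero(self, rng):
        es = EpochSet(data=rng.standard_normal((5, 2, 1200)))
        r = baseline_subtract(trim_edges(morlet_tfr(es)))
        mask = (r.times_ms >= -600) & (r.times_ms < -100)
        assert np.max(np.abs(r.amplitude[:, :, mask].mean(axis=2))) < 1e-9

    def test_stationary_signal_corrects_to_zero(self):
        r = baseline_subtract(trim_edges(morlet_tfr(_sine_epochs(amp=3.0))))
        k = 4  # 7 Hz bin
        assert np.max(np.abs(r.amplitude[0, k])) < 0.05

    def test_double_correction_errors(self):
        r = baseline_subtract(trim_edges(morlet_tfr(_sine_epochs())))
        with pytest.raises(TimeFrequencyError):
            baseline_subtract(r)

    def test_window_outside_range_errors(self):
        r = trim_edges(morlet_tfr(_sine_epochs()))
        with pytest.raises(TimeFrequencyError):
            baseline_subtract(r, -900.0, -700.0)


class TestBandClusterMean:
    def test_band_is_four_inclusive_bins(self):
        freqs = np.arange(3.0, 21.0)
        assert list(freqs[band_indices(freqs, (6, 9))]) == [6.0, 7.0, 8.0, 9.0]

    def test_constant_value_recovered(self, montage128):
        from munet.timefreq import TimeFrequencyRep

        labels = montage128.cluster_channels("C4")
        times = np.arange(-600.0, 1000.0, 2.0)
        rep = TimeFrequencyRep(
            amplitude=np.full((labels.size, 18, times.size), -0.25),
            freqs=np.arange(3.0, 21.0),
            times_ms=times,
            labels=labels,
            baseline_corrected=True,
            trimmed=True,
        )
        assert band_cluster_mean(rep, montage128, "C4") == pytest.approx(-0.25)

    def test_unknown_cluster_errors(self, montage128):
        r = baseline_subtract(trim_edges(morlet_tfr(_sine_epochs())))
        with pytest.raises(KeyError):
            band_cluster_mean(r, montage128, "FCz")

    def test_requires_baseline_state(self, montage128):
        r = trim_edges(morlet_tfr(_sine_epochs(n_channels=128)))
        with pytest.raises(TimeFrequencyError):
            band_cluster_mean(r, montage128, "C4")


def test_injected_erd_envelope_measured(montage128):
    """A -0.3 µV amplitude drop in the analysis window is read back as -0.3."""
    fs, n = 500.0, 1200
    t_ms = -1000.0 + np.arange(n) * 1000.0 / fs
    amp = np.full(n, 5.0)
    plateau = (t_ms >= 200.0) & (t_ms <= 1000.0)
    amp[plateau] -= 0.3
    t = np.arange(n) / fs
    rng = np.random.default_rng(0)
    trials = []
    for _ in range(60):
        phase = rng.uniform(0, 2 * np.pi)
        trials.append(amp * np.cos(2 * np.pi * 7.0 * t + phase))
    es = EpochSet(data=np.asarray(trials)[:, None, :])
    r = baseline_subtract(trim_edges(morlet_tfr(es)))
    k = int(np.flatnonzero(r.freqs == 7.0)[0])
    mask = (r.times_ms >= 400) & (r.times_ms <= 800)
    assert r.amplitude[0, k, mask].mean() == pytest.approx(-0.3, abs=0.03)
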