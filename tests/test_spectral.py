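"""Epoch extraction, Parseval-scaled spectra, and the SSVEP SNR statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssvepnet import compute_snr, extract_epochs, power_spectrum
from ssvepnet.montage import stimulus_frequency
from ssvepnet.spectral import EmptySegmentError, EpochSet, stimulus_bin


def sine(freq, fs, dur, amp=1.0, phase=0.0):
    t = np.arange(int(round(dur * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestStimulusFrequency:
    def test_cycle_durations_give_study_frequencies(self):
        assert stimulus_frequency(0.080) == pytest.approx(12.5)
        assert stimulus_frequency(0.060) == pytest.approx(1000.0 / 60.0)

    def test_nonpositive_cycle_rejected(self):
        with pytest.raises(ValueError):
            stimulus_frequency(0.0)


class TestExtractEpochs:
    def test_six_second_segment_gives_four_epochs(self):
        seg = np.zeros((2, 1500))
        es = extract_epochs(seg, fs=250, window_s=2.4, overlap_s=1.2)
        assert es.n_epochs == 4
        assert es.epochs.shape == (4, 2, 600)
        # start times are multiples of window - overlap = 1.2 s
        marker = np.zeros((1, 1500))
        marker[0, [0, 300, 600, 900]] = [1, 2, 3, 4]
        es = extract_epochs(marker, fs=250, window_s=2.4, overlap_s=1.2)
        assert [e[0, 0] for e in es.epochs] == [1, 2, 3, 4]

    def test_exact_window_gives_single_epoch(self):
        es = extract_epochs(np.zeros((1, 600)), fs=250)
        assert es.n_epochs == 1

    def test_short_segment_is_an_error(self):
        with pytest.raises(EmptySegmentError):
            extract_epochs(np.zeros((1, 599)), fs=250)

    @settings(derandomize=True, max_examples=80)
    @given(
        n_win=st.integers(10, 200),
        n_extra=st.integers(0, 500),
        step_frac=st.integers(1, 10),
    )
    def test_epoch_count_matches_enumeration(self, n_win, n_extra, step_frac):
        """count = floor((T - window) / (window - overlap)) + 1, vs brute force."""
        fs = 10.0
        step = max(1, n_win * step_frac // 10)
        overlap = n_win - step
        n_total = n_win + n_extra
        es = extract_epochs(
            np.zeros((1, n_total)), fs, window_s=n_win / fs, overlap_s=overlap / fs
        )
        brute = len([s for s in range(0, n_total + 1, step) if s + n_win <= n_total])
        formula = (n_total - n_win) // step + 1
        assert es.n_epochs == brute == formula

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            extract_epochs(np.zeros((1, 1500)), 250, window_s=2.4, overlap_s=2.4)
        with pytest.raises(ValueError):
            EpochSet(np.zeros((1, 1, 10)), window_s=1.0, overlap_s=-0.1, fs=10)


class TestPowerSpectrum:
    def test_integer_cycle_sinusoid_concentrates_on_one_bin(self):
        x = sine(12.5, 250, 2.4)
        freqs, p = power_spectrum(x, 250)
        b = stimulus_bin(freqs, 12.5)
        assert b == 30  # 12.5 Hz * 2.4 s
        assert freqs[1] == pytest.approx(1 / 2.4)
        assert p[0, b] == pytest.approx(0.5, rel=1e-9)  # mean square of unit sine
        off = np.delete(p[0], b)
        assert np.all(off < 1e-16)

    def test_parseval_identity(self, rng):
        x = rng.normal(size=(3, 601))  # odd length exercises the Nyquist branch
        _, p = power_spectrum(x, 250)
        assert np.allclose(p.sum(axis=-1), (x**2).mean(axis=-1))


class TestSNR:
    def epochs_of(self, x, fs=250.0):
        x = np.atleast_2d(x)
        return EpochSet(x[None, :, :], window_s=x.shape[-1] / fs,
                        overlap_s=0.0, fs=fs)

    def test_flat_spectrum_gives_unit_snr(self):
        # an impulse has exactly equal power in every bin
        x = np.zeros((4, 600))
        x[:, 0] = 1.0
        rec = compute_snr(self.epochs_of(x), stim_freq=12.5)
        assert np.allclose(rec.per_channel_snr, 1.0)
        assert rec.mean_snr == pytest.approx(1.0)

    def test_snr_band_is_two_bins_at_study_resolution(self):
        # only power at 12.5 +- 1/2.4 Hz counts as noise
        x = sine(12.5, 250, 2.4, amp=2.0) + sine(12.5 - 1 / 2.4, 250, 2.4)
        rec = compute_snr(self.epochs_of(x), stim_freq=12.5)
        # signal power 2.0, band = mean(0.5, 0) = 0.25 -> SNR 8
        assert rec.mean_snr == pytest.approx(8.0, rel=1e-6)

    def test_snr_is_scale_invariant(self, rng):
        x = sine(12.5, 250, 2.4) + 0.3 * rng.normal(size=600)
        a = compute_snr(self.epochs_of(x), 12.5).mean_snr
        b = compute_snr(self.epochs_of(17.0 * x), 12.5).mean_snr
        assert a == pytest.approx(b, rel=1e-9)

    def test_mean_snr_averages_channels(self, rng):
        x = np.stack([sine(12.5, 250, 2.4, amp=a) for a in (1, 2, 3)])
        x = x + 0.1 * rng.normal(size=x.shape)
        rec = compute_snr(self.epochs_of(x), 12.5)
        assert rec.mean_snr == pytest.approx(rec.per_channel_snr.mean())
        assert len(rec.per_channel_snr) == 3

    def test_zero_noise_band_reports_infinite_snr(self):
        # a zero-power noise band must signal, not silently clip
        rec = compute_snr(self.epochs_of(np.zeros((2, 600))), 12.5)
        assert np.all(np.isinf(rec.per_channel_snr))

    def test_pure_noise_snr_mean_matches_ratio_statistics(self, rng):
        """E[SNR] of white noise is k/(k-1) for a k-bin noise band.

        Bin powers of Gaussian noise are iid exponentials, and
        E[X / mean(Y_1..Y_k)] = k/(k-1); the often-quoted 'pure noise has
        SNR 1' holds only in the many-bin limit.  At the study resolution
        (2.4 s epochs) the band has k = 2 bins, so the mean is 2; with a
        24 s epoch the band has k = 24 bins and the mean approaches 1.
        """
        for dur, k in ((2.4, 2), (24.0, 24)):
            vals = []
            for _ in range(500):
                x = rng.normal(size=(1, int(250 * dur)))
                vals.append(compute_snr(self.epochs_of(x), 12.5).mean_snr)
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - k / (k - 1)) < 3 * se

    def test_snr_matches_independent_fft_computation(self, rng):
        """Cross-check against a from-scratch FFT evaluation of the ratio."""
        for _ in range(100):
            x = sine(12.5, 250, 2.4, amp=rng.uniform(0.5, 3)) + rng.normal(
                0, 0.5, size=600
            )
            mine = compute_snr(self.epochs_of(x), 12.5).mean_snr
            spec = np.abs(np.fft.fft(x)) ** 2  # any scaling cancels in the ratio
            freqs = np.fft.fftfreq(600, 1 / 250.0)
            b = np.argmin(np.abs(freqs[:300] - 12.5))
            band = [
                k for k in range(300)
                if abs(freqs[k] - 12.5) <= 0.5 + 1e-9 and k != b
            ]
            oracle = spec[b] / spec[band].mean()
            assert mine == pytest.approx(oracle, rel=1e-9)

    def test_stim_freq_outside_range_rejected(self):
        with pytest.raises(ValueError):
            compute_snr(self.epochs_of(np.zeros((1, 600))), stim_freq=200.0)
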