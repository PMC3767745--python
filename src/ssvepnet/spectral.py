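"""Epoch extraction, narrow-band power spectra, and the SSVEP SNR statistic.

The SSVEP response is quantified as a signal-to-noise ratio: power at the
stimulus-frequency FFT bin divided by the mean power of the surrounding
1 Hz band excluding that bin.  With 2.4 s epochs the bin spacing is
1/2.4 ≈ 0.4167 Hz, so both 12.5 Hz and 16.67 Hz fall exactly on bins (an
integer number of stimulus cycles fits in the window) and the 1 Hz band
discretizes to the two adjacent bins.  Epochs are analysed with a
rectangular window: integer-cycle alignment makes spectral leakage of the
stimulus component exactly zero, so no taper is needed for the SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Recording

__all__ = [
    "EpochSet",
    "SNRRecord",
    "extract_epochs",
    "epochs_from_recording",
    "power_spectrum",
    "compute_snr",
    "stimulus_bin",
]


class EmptySegmentError(ValueError):
    """Raised when a segment is too short to contain a single window."""


@dataclass
class EpochSet:
    """Fixed-length windows cut from one or more segments.

    ``epochs`` has shape ``(n_epochs, n_channels, window_samples)``.
    """

    epochs: np.ndarray
    window_s: float
    overlap_s: float
    fs: float

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError(f"epochs must be 3-d, got shape {self.epochs.shape}")
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError(
                f"need 0 <= overlap ({self.overlap_s}) < window ({self.window_s})"
            )
        n_win = self.window_s * self.fs
        if abs(n_win - round(n_win)) > 1e-9:
            raise ValueError(f"window_s * fs = {n_win} is not an integer")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class SNRRecord:
    """Stimulus-band SNR per channel and its channel average."""

    per_channel_snr: np.ndarray
    mean_snr: float
    stim_freq: float


def _samples(duration_s: float, fs: float, what: str) -> int:
    n = duration_s * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{what} of {duration_s} s is not an integer number of samples at fs={fs}")
    return int(round(n))


def extract_epochs(
    segment: np.ndarray,
    fs: float,
    window_s: float = 2.4,
    overlap_s: float = 1.2,
) -> EpochSet:
    """Cut one ``(n_channels, n_samples)`` segment into overlapping epochs.

    Epochs start at multiples of ``window_s - overlap_s``; only fully
    contained windows are emitted, so a segment of duration ``T`` yields
    ``floor((T - window) / (window - overlap)) + 1`` epochs.  A 6 s segment
    with 2.4 s windows and 1.2 s overlap yields 4 epochs starting at 0.0,
    1.2, 2.4 and 3.6 s.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if not 0 <= overlap_s < window_s:
        raise ValueError(f"need 0 <= overlap ({overlap_s}) < window ({window_s})")
    n_win = _samples(window_s, fs, "window")
    n_step = n_win - _samples(overlap_s, fs, "overlap")
    n_total = segment.shape[1]
    if n_total < n_win:
        raise EmptySegmentError(
            f"segment of {n_total} samples is shorter than one "
            f"{n_win}-sample window"
        )
    starts = range(0, n_total - n_win + 1, n_step)
    epochs = np.stack([segment[:, s : s + n_win] for s in starts])
    return EpochSet(epochs=epochs, window_s=window_s, overlap_s=overlap_s, fs=fs)


def epochs_from_recording(
    recording: Recording,
    window_s: float = 2.4,
    overlap_s: float = 1.2,
) -> EpochSet:
    """All epochs of a recording, concatenated across its segments."""
    if not recording.segments:
        raise EmptySegmentError("recording has no segments")
    parts = [
        extract_epochs(seg, recording.fs, window_s, overlap_s).epochs
        for seg in recording.segments
    ]
    return EpochSet(
        epochs=np.concatenate(parts, axis=0),
        window_s=window_s,
        overlap_s=overlap_s,
        fs=recording.fs,
    )


def power_spectrum(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of an epoch, scaled to satisfy Parseval.

    Returns ``(freqs, power)`` with ``power`` of shape
    ``(n_channels, n_bins)``; ``power.sum(axis=-1)`` equals the mean square
    of the corresponding channel.  Bin spacing is ``1 / epoch_duration``.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n = epoch.shape[-1]
    if n == 0:
        raise ValueError("empty epoch")
    spec = np.fft.rfft(epoch, axis=-1)
    power = np.abs(spec) ** 2 / n**2
    # One-sided: interior bins absorb their negative-frequency twins.
    scale = np.full(power.shape[-1], 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = power * scale
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def stimulus_bin(freqs: np.ndarray, stim_freq: float) -> int:
    """Index of the FFT bin nearest the stimulus frequency."""
    return int(np.argmin(np.abs(freqs - stim_freq)))


def compute_snr(
    epochs: EpochSet,
    stim_freq: float,
    band_hz: float = 1.0,
) -> SNRRecord:
    """Stimulus-band SNR from an epoch set.

    Per epoch and channel, SNR is the power at the bin nearest ``stim_freq``
    divided by the mean power over all bins within ``band_hz / 2`` of the
    stimulus frequency, excluding the stimulus bin itself.  Per-channel SNRs
    are averaged over epochs, then across channels for ``mean_snr``.  A zero
    noise-band power yields ``inf`` (reported, not clipped).
    """
    freqs, _ = power_spectrum(epochs.epochs[0], epochs.fs)
    if not freqs[0] <= stim_freq <= freqs[-1]:
        raise ValueError(
            f"stimulus frequency {stim_freq} Hz outside spectral range "
            f"[{freqs[0]}, {freqs[-1]}]"
        )
    b0 = stimulus_bin(freqs, stim_freq)
    band = np.flatnonzero(np.abs(freqs - stim_freq) <= band_hz / 2 + 1e-9)
    band = band[band != b0]
    if band.size == 0:
        raise ValueError(
            f"no neighbouring bin within ±{band_hz / 2} Hz of {stim_freq} Hz; "
            "epoch too short for the requested band"
        )
    snrs = []
    for epoch in epochs.epochs:
        _, p = power_spectrum(epoch, epochs.fs)
        noise = p[:, band].mean(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(noise > 0, p[:, b0] / np.where(noise > 0, noise, 1.0), np.inf)
        snrs.append(ratio)
    per_channel = np.mean(snrs, axis=0)
    return SNRRecord(
        per_channel_snr=per_channel,
        mean_snr=float(np.mean(per_channel)),
        stim_freq=stim_freq,
    )
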