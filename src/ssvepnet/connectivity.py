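"""Narrow-band magnitude-squared coherence networks.

Coherence between channels x and y at frequency f is

    w_xy = |C_xy(f)|^2 / (C_xx(f) C_yy(f)),

with cross- and auto-spectra estimated Welch-style by averaging over tapered
sub-windows.  A single sub-window gives coherence identically 1, so each
2.4 s epoch is split into 1.2 s Hann sub-windows with 50% overlap (three per
epoch by default); 1.2 s still holds an integer number of cycles of both
12.5 and 16.67 Hz stimuli.  The estimate is evaluated at the single FFT bin
nearest the stimulus frequency — SSVEP power is confined to a very narrow
band, so one bin captures the response.

Per-epoch networks are averaged into one "original whole network" per
subject and condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .recording import Recording
from .spectral import EpochSet, epochs_from_recording

__all__ = [
    "CoherenceNetwork",
    "epoch_coherence",
    "average_networks",
    "recording_network",
]


class UndefinedCoherenceError(ValueError):
    """Raised when a channel has zero auto-spectrum at the stimulus bin."""


@dataclass
class CoherenceNetwork:
    """Symmetric nonnegative weighted network over an electrode montage.

    ``weights[i, j]`` is the coherence (or derived weight) between channels
    ``node_labels[i]`` and ``node_labels[j]``; the diagonal is 0 by
    convention (self-loops carry no network information).
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    stim_freq: float
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-9):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def edge_weight(self, a: str, b: str) -> float:
        i = self.node_labels.index(a)
        j = self.node_labels.index(b)
        return float(self.weights[i, j])


def _subwindow_fft_at_bin(
    epoch: np.ndarray,
    fs: float,
    stim_freq: float,
    subwindow_s: float,
    sub_overlap_frac: float,
    taper: str,
) -> np.ndarray:
    """Tapered sub-window FFT coefficients at the stimulus bin, (K, C)."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n = epoch.shape[-1]
    n_sub = int(round(subwindow_s * fs))
    if n_sub < 2 or n_sub > n:
        raise ValueError(
            f"sub-window of {n_sub} samples invalid for epoch of {n}"
        )
    step = n_sub - int(round(n_sub * sub_overlap_frac))
    if step < 1:
        raise ValueError(f"sub-window overlap fraction {sub_overlap_frac} too large")
    starts = range(0, n - n_sub + 1, step)
    if len(starts) < 2:
        raise ValueError(
            "coherence needs >= 2 sub-windows (one sub-window is identically 1); "
            f"epoch of {n} samples gives {len(starts)}"
        )
    win = get_window(taper, n_sub, fftbins=True)
    freqs = np.fft.rfftfreq(n_sub, d=1.0 / fs)
    b = int(np.argmin(np.abs(freqs - stim_freq)))
    segs = np.stack([epoch[:, s : s + n_sub] for s in starts])  # (K, C, n_sub)
    return np.fft.rfft(segs * win, axis=-1)[:, :, b]


def epoch_coherence(
    epoch: np.ndarray,
    fs: float,
    stim_freq: float,
    subwindow_s: float = 1.2,
    sub_overlap_frac: float = 0.5,
    taper: str = "hann",
    node_labels: tuple[str, ...] | None = None,
) -> CoherenceNetwork:
    """All-pairs magnitude-squared coherence of one epoch at the stimulus bin.

    ``coh_ij = |mean_k X_ik conj(X_jk)|^2 / (mean_k |X_ik|^2 mean_k |X_jk|^2)``
    over sub-windows k.  Output is symmetric with zero diagonal and weights
    in [0, 1].
    """
    F = _subwindow_fft_at_bin(
        epoch, fs, stim_freq, subwindow_s, sub_overlap_frac, taper
    )  # (K, C)
    C = F.shape[1]
    cross = np.einsum("kc,kd->cd", F, F.conj()) / F.shape[0]
    auto = np.real(np.diag(cross)).copy()
    if np.any(auto <= 0):
        labels = node_labels or tuple(f"ch{i}" for i in range(C))
        bad = [labels[i] for i in np.flatnonzero(auto <= 0)]
        raise UndefinedCoherenceError(
            f"zero auto-spectrum at {stim_freq} Hz for channel(s) {bad}; "
            "coherence undefined"
        )
    coh = np.abs(cross) ** 2 / np.outer(auto, auto)
    coh = 0.5 * (coh + coh.T)  # symmetrize away rounding noise
    np.fill_diagonal(coh, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    if node_labels is None:
        node_labels = tuple(f"ch{i}" for i in range(C))
    return CoherenceNetwork(
        node_labels=node_labels,
        weights=coh,
        stim_freq=stim_freq,
        n_epochs_averaged=1,
    )


def average_networks(networks: list[CoherenceNetwork]) -> CoherenceNetwork:
    """Element-wise mean of per-epoch networks sharing labels and frequency."""
    if not networks:
        raise ValueError("cannot average an empty list of networks")
    first = networks[0]
    for net in networks[1:]:
        if net.node_labels != first.node_labels:
            raise ValueError("networks have mismatched node labels")
        if net.stim_freq != first.stim_freq:
            raise ValueError("networks have mismatched stimulus frequencies")
    mean = np.mean([net.weights for net in networks], axis=0)
    return CoherenceNetwork(
        node_labels=first.node_labels,
        weights=mean,
        stim_freq=first.stim_freq,
        n_epochs_averaged=len(networks),
    )


def recording_network(
    recording: Recording,
    stim_freq: float,
    window_s: float = 2.4,
    overlap_s: float = 1.2,
    subwindow_s: float = 1.2,
    sub_overlap_frac: float = 0.5,
    taper: str = "hann",
) -> CoherenceNetwork:
    """Per-subject original whole network: mean of all per-epoch networks."""
    epochs: EpochSet = epochs_from_recording(recording, window_s, overlap_s)
    nets = [
        epoch_coherence(
            ep,
            recording.fs,
            stim_freq,
            subwindow_s,
            sub_overlap_frac,
            taper,
            node_labels=recording.channel_labels,
        )
        for ep in epochs.epochs
    ]
    return average_networks(nets)
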