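"""The in-memory container for one subject/condition's recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Artifact-free data segments for one subject under one stimulus condition.

    Attributes
    ----------
    subject
        Subject identifier, e.g. ``"S03"``.
    condition
        Condition label, conventionally the stimulus frequency, e.g.
        ``"12.5Hz"``.
    fs
        Sampling rate in samples/s.
    channel_labels
        One label per row of every segment.
    segments
        List of ``(n_channels, n_samples)`` float arrays.  All segments share
        the same shape.
    """

    subject: str
    condition: str
    fs: float
    channel_labels: tuple[str, ...]
    segments: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n_ch = len(self.channel_labels)
        for k, seg in enumerate(self.segments):
            if seg.ndim != 2 or seg.shape[0] != n_ch:
                raise ValueError(
                    f"segment {k} has shape {seg.shape}; expected "
                    f"({n_ch}, n_samples)"
                )
        if self.segments:
            n_samp = {seg.shape[1] for seg in self.segments}
            if len(n_samp) != 1:
                raise ValueError(f"segments differ in length: {sorted(n_samp)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_segments(self) -> int:
        return len(self.segments)
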