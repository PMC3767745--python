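"""Stimulus-band SNR from epoched recordings.

Cuts one subject's segments into 2.4 s epochs with 1.2 s overlap, computes
the Parseval-scaled power spectrum, and reports the SSVEP response as SNR:
power at the 12.5 Hz bin over the mean power of the surrounding 1 Hz band.
"""

import numpy as np

from ssvepnet import (
    GeneratorConfig, compute_snr, epochs_from_recording, generate_subject,
    power_spectrum,
)
from ssvepnet.spectral import stimulus_bin

config = GeneratorConfig(seed=0)
weak = generate_subject(config, 0)    # smallest entrainment gain (0.5)
strong = generate_subject(config, 10)  # largest gain (2.0)

for name, rec in (("weak", weak), ("strong", strong)):
    epochs = epochs_from_recording(rec, window_s=2.4, overlap_s=1.2)
    freqs, power = power_spectrum(epochs.epochs[0], rec.fs)
    b = stimulus_bin(freqs, 12.5)
    snr = compute_snr(epochs, stim_freq=12.5)
    print(f"{name} subject: {epochs.n_epochs} epochs; "
          f"bin spacing {freqs[1]:.4f} Hz; stimulus bin {b} "
          f"({freqs[b]:g} Hz exactly on-bin)")
    print(f"  mean SNR over {len(snr.per_channel_snr)} channels: "
          f"{snr.mean_snr:.1f} "
          f"(channel range {snr.per_channel_snr.min():.1f}-"
          f"{snr.per_channel_snr.max():.1f})")
# The strongly entrained subject shows a several-fold larger SNR: the
# flicker-locked component grows with the entrainment gain while the
# neighbouring noise band does not.
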