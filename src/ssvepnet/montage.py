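"""Electrode montage and stimulus bookkeeping.

The analysis operates on 18 widely spaced electrodes of the international
10-20 system.  Wide spacing keeps scalp coherence interpretable: closely
spaced pairs are dominated by volume conduction rather than genuine
functional coupling.
"""

from __future__ import annotations

#: 18-node montage used for network construction (frontal to occipital order).
MONTAGE_18: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


def stimulus_frequency(cycle_s: float) -> float:
    """Fundamental frequency (Hz) of a periodic stimulus with cycle ``cycle_s``.

    An LED driven with an 80 ms on/off cycle flickers at 1/0.080 = 12.5 Hz;
    a 60 ms cycle gives 16.67 Hz.

    Parameters
    ----------
    cycle_s
        Duration of one full stimulus cycle in seconds; must be positive.
    """
    if cycle_s <= 0:
        raise ValueError(f"stimulus cycle must be positive, got {cycle_s}")
    return 1.0 / cycle_s
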