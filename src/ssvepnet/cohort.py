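"""Synthetic steady-state cohort generator with known ground truth.

Emulates a frequency-tagging experiment: each subject views a flicker at a
fixed frequency and every EEG channel entrains to it with a subject-specific
gain ``g_s``.  Each channel superimposes four components:

* a *stimulus-locked tone* at the flicker frequency (plus an optional second
  harmonic), amplitude ``∝ g_s``, with a phase redrawn per segment but
  constant within it.  Locked within-segment phase means zero spectral
  leakage, so against the broadband noise floor this component makes the
  stimulus-band SNR grow monotonically with ``g_s``;
* a per-channel *narrow-band dilution* source: a wide-band jittered tone
  modelling non-locked background rhythms near the stimulus frequency.  It
  dilutes the otherwise perfect sub-window coherence of the locked tones;
  its amplitude ``∝ g_s^dilution_exponent`` shrinks with entrainment by
  default (event-related desynchronization of the background), so baseline
  coherence of *every* pair drifts upward with the subject's entrainment —
  the diffuse network-wide trend the non-significant edge mass shows in
  real recordings.  With exponent 1 the locked fraction of narrow-band
  power — and hence the expected coherence — is the same for every subject
  (the trend-free null used for calibration);
* *shared* narrow-band sources injected on planted edges, mixing weight
  ``∝ g_s²`` on positive edges and ``∝ 1/g_s`` on negative edges (optional
  weak background sources on the remaining pairs are available but off by
  default).  Shared power between two channels creates coherence
  specifically at the stimulus bin;
* independent broadband Gaussian noise.

Coherence between two channels at the stimulus bin is governed by the ratio
of coherent (locked + shared) to incoherent narrow-band power.  Because the
locked amplitude scales as ``g_s``, a shared mixing weight ``∝ g_s`` would
leave that ratio flat in ``g_s``; the ``g_s²`` (positive) and ``1/g_s``
(negative) laws make edge strength genuinely increase or decrease with the
subject's entrainment, and hence with stimulus-band SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import MONTAGE_18
from .recording import Recording

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_subject",
    "generate_cohort",
    "DEFAULT_POS_EDGES",
    "DEFAULT_NEG_EDGES",
]

#: Default planted positively coupled edges: long-range parieto-occipital to
#: frontal pairs, the links a flicker-entrained network strengthens most.
#: All planted edges are node-disjoint: two shared sources on one channel
#: dilute each other's coherence and flatten the very trend being planted.
DEFAULT_POS_EDGES: tuple[tuple[str, str], ...] = (
    ("O1", "F3"),
    ("O2", "F4"),
    ("P3", "Fp1"),
    ("P4", "Fp2"),
    ("Pz", "Fz"),
)

#: Default planted negatively coupled edges (sparse, as negative links are in
#: scalp coherence studies); node-disjoint from the positive set.
DEFAULT_NEG_EDGES: tuple[tuple[str, str], ...] = (
    ("T5", "F7"),
    ("T6", "F8"),
)


def _norm_edge(edge: tuple[str, str]) -> tuple[str, str]:
    a, b = edge
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 11 subjects, 12.5 Hz flicker,
    250 Hz sampling, 18 channels, 12 artifact-free 6 s segments each.
    """

    n_subjects: int = 11
    stim_freq: float = 12.5
    fs: float = 250.0
    n_channels: int = 18
    n_segments: int = 12
    segment_s: float = 6.0
    #: Per-subject entrainment gains g_s > 0; None -> linspace(0.5, 2.0).
    entrain_factors: tuple[float, ...] | None = None
    pos_edges: tuple[tuple[str, str], ...] = DEFAULT_POS_EDGES
    neg_edges: tuple[tuple[str, str], ...] = DEFAULT_NEG_EDGES
    noise_sd: float = 1.0
    #: Optional per-subject broadband noise sd overriding ``noise_sd``
    #: (models between-subject differences in recording quality).
    noise_sd_per_subject: tuple[float, ...] | None = None
    #: Stimulus-locked tone base amplitude (actual amplitude = amplitude *
    #: g_s * exp(N(0, amplitude_spread)), one lognormal gain per (channel,
    #: subject)): the spread models idiosyncratic per-electrode response
    #: strength.
    amplitude: float = 1.2
    amplitude_spread: float = 0.15
    harmonic_amp: float = 0.25
    #: Phase random-walk step sd (rad/sample) of the shared narrow-band
    #: sources, wide enough to decorrelate 1.2 s coherence sub-windows while
    #: keeping most of the source's power inside the stimulus bin.
    phase_jitter: float = 0.06
    #: Per-channel dilution amplitude = dilution * g_s**dilution_exponent
    #: * exp(N(0, dilution_spread)) with one lognormal gain per (channel,
    #: subject).  The dilution models non-locked background rhythms near the
    #: stimulus frequency (the alpha band, for stimuli in its range); the
    #: negative default exponent encodes that stronger entrainment
    #: suppresses this idiosyncratic background (event-related alpha
    #: desynchronization), which both steepens the SNR–gain relation and
    #: compresses weight dispersion in strongly entrained subjects.
    #: Exponent 1 instead makes the locked fraction of narrow-band power —
    #: and the expected coherence of every pair — gain-free (the
    #: calibration null).
    dilution: float = 1.4
    dilution_exponent: float = -0.5
    dilution_spread: float = 0.4
    #: Phase random-walk step sd of the dilution sources.  Deliberately
    #: wider-band than the shared sources: the dilution should raise the
    #: incoherent narrow-band floor at the stimulus bin without itself
    #: looking like a stimulus response (its in-bin to side-band power
    #: ratio stays near 1, so it does not put a floor under the SNR).
    dilution_jitter: float = 0.35
    #: Mixing of planted positive edges: weight = coupling_base +
    #: coupling * g_s**2.  The constant base keeps positive edges strong in
    #: every subject (so they anchor the weight scale of Network 1) while
    #: the quadratic term makes them grow with entrainment.
    coupling: float = 1.5
    coupling_base: float = 0.0
    #: Base mixing of planted negative edges (weight = neg_coupling / g_s).
    #: Large enough that the shared power's decline beats the locked tone's
    #: rise at every gain in the default range, keeping the edge's coherence
    #: monotonically decreasing.
    neg_coupling: float = 6.0
    #: Base mixing of weak shared sources on all non-planted pairs (weight =
    #: background_coupling * g_s**background_exponent * lognormal gain);
    #: 0 (default) disables them: the diffuse positive weight–SNR trend of
    #: non-planted edges already arises from the locked narrow-band fraction
    #: growing with g_s.
    background_coupling: float = 0.0
    background_exponent: float = 1.3
    #: Lognormal sigma of the per-(edge, subject) background gain.
    background_spread: float = 0.75
    channel_labels: tuple[str, ...] = MONTAGE_18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.n_channels} channels"
            )
        n = self.segment_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"segment_s * fs = {n} is not an integer number of samples"
            )
        pos = {_norm_edge(e) for e in self.pos_edges}
        neg = {_norm_edge(e) for e in self.neg_edges}
        if pos & neg:
            raise ValueError(f"edges planted in both classes: {pos & neg}")
        known = set(self.channel_labels)
        for a, b in list(pos) + list(neg):
            if a not in known or b not in known:
                raise ValueError(f"planted edge ({a}, {b}) not in montage")
            if a == b:
                raise ValueError(f"self-edge ({a}, {b}) not allowed")
        for g in self.gains():
            if g <= 0:
                raise ValueError("all entrainment factors must be positive")
        if self.noise_sd_per_subject is not None and len(
            self.noise_sd_per_subject
        ) != self.n_subjects:
            raise ValueError(
                "noise_sd_per_subject must have one entry per subject"
            )

    def gains(self) -> np.ndarray:
        """Per-subject entrainment gains as an array."""
        if self.entrain_factors is not None:
            g = np.asarray(self.entrain_factors, dtype=float)
            if g.shape != (self.n_subjects,):
                raise ValueError(
                    f"entrain_factors has shape {g.shape}; expected "
                    f"({self.n_subjects},)"
                )
            return g
        return np.linspace(0.5, 2.0, self.n_subjects)

    @property
    def n_samples(self) -> int:
        return int(round(self.segment_s * self.fs))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: gains and the class of every channel pair."""

    entrain_factors: tuple[float, ...]
    #: Unordered pair (labels sorted) -> "positive" | "negative" | "null".
    edge_class: dict[tuple[str, str], str] = field(default_factory=dict)

    def planted(self, cls: str) -> list[tuple[str, str]]:
        return [e for e, c in self.edge_class.items() if c == cls]


def _jittered_tone(
    rng: np.random.Generator,
    freq: float,
    fs: float,
    n: int,
    phase0: np.ndarray | float,
    jitter_sd: float,
    shape: tuple[int, ...] = (),
) -> np.ndarray:
    """Sinusoid(s) with a random-walk phase; shape ``shape + (n,)``."""
    t = np.arange(n) / fs
    base = 2.0 * np.pi * freq * t
    if jitter_sd > 0:
        drift = np.cumsum(
            rng.normal(0.0, jitter_sd, size=shape + (n,)), axis=-1
        )
    else:
        drift = np.zeros(shape + (n,))
    return np.sin(base + np.atleast_1d(np.asarray(phase0))[..., None] + drift)


def _subject_rng(config: GeneratorConfig, subject_index: int) -> np.random.Generator:
    # Streams are keyed on (seed, subject, stimulus frequency in mHz) so the
    # two conditions of one subject do not share a noise realization.
    return np.random.default_rng(
        [int(config.seed), int(subject_index), int(round(config.stim_freq * 1000))]
    )


def generate_subject(config: GeneratorConfig, subject_index: int) -> Recording:
    """Generate one subject's segments under ``config``.

    Deterministic given ``(config.seed, subject_index, config.stim_freq)``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} out of range "
            f"[0, {config.n_subjects})"
        )
    g = float(config.gains()[subject_index])
    rng = _subject_rng(config, subject_index)
    labels = config.channel_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    C, n, fs, f0 = config.n_channels, config.n_samples, config.fs, config.stim_freq
    t = np.arange(n) / fs

    pos = [tuple(map(idx.__getitem__, _norm_edge(e))) for e in config.pos_edges]
    neg = [tuple(map(idx.__getitem__, _norm_edge(e))) for e in config.neg_edges]
    planted_pairs = list(pos) + list(neg)
    planted_mix = np.array(
        [config.coupling_base + config.coupling * g**2] * len(pos)
        + [config.neg_coupling / g] * len(neg)
    )

    if config.background_coupling > 0:
        planted_set = {tuple(sorted(p)) for p in planted_pairs}
        bg_pairs = [
            (i, j)
            for i in range(C)
            for j in range(i + 1, C)
            if (i, j) not in planted_set
        ]
        # Per-(edge, subject) lognormal gain, drawn once per subject.
        bg_gain = np.exp(
            rng.normal(0.0, config.background_spread, size=len(bg_pairs))
        )
        bg_mix = (
            config.background_coupling * g**config.background_exponent * bg_gain
        )
    else:
        bg_pairs, bg_mix = [], np.empty(0)

    all_pairs = planted_pairs + bg_pairs
    all_mix = np.concatenate([planted_mix, bg_mix]) if all_pairs else np.empty(0)
    src_i = np.array([p[0] for p in all_pairs], dtype=int)
    src_j = np.array([p[1] for p in all_pairs], dtype=int)

    noise_sd = (
        config.noise_sd_per_subject[subject_index]
        if config.noise_sd_per_subject is not None
        else config.noise_sd
    )
    tone_amp = config.amplitude * g * np.ones(C)
    if config.amplitude_spread > 0:
        tone_amp *= np.exp(rng.normal(0.0, config.amplitude_spread, size=C))
    dil_amp = config.dilution * g**config.dilution_exponent * np.ones(C)
    if config.dilution_spread > 0:
        dil_amp *= np.exp(rng.normal(0.0, config.dilution_spread, size=C))
    segments: list[np.ndarray] = []
    for _ in range(config.n_segments):
        # Stimulus-locked tones: phase constant within the segment (zero
        # leakage), redrawn across segments so tone-phase interference with
        # the shared sources averages out over epochs.
        phase_fund = rng.uniform(0.0, 2.0 * np.pi, size=C)
        x = tone_amp[:, None] * np.sin(2.0 * np.pi * f0 * t + phase_fund[:, None])
        if config.harmonic_amp > 0:
            phase_harm = rng.uniform(0.0, 2.0 * np.pi, size=C)
            x += (config.harmonic_amp * tone_amp)[:, None] * np.sin(
                4.0 * np.pi * f0 * t + phase_harm[:, None]
            )
        if config.dilution > 0:
            x += dil_amp[:, None] * _jittered_tone(
                rng, f0, fs, n,
                rng.uniform(0.0, 2.0 * np.pi, size=C),
                config.dilution_jitter, shape=(C,),
            )
        if all_pairs:
            theta = rng.uniform(0.0, 2.0 * np.pi, size=len(all_pairs))
            u = all_mix[:, None] * _jittered_tone(
                rng, f0, fs, n, theta, config.phase_jitter,
                shape=(len(all_pairs),),
            )
            np.add.at(x, src_i, u)
            np.add.at(x, src_j, u)
        if noise_sd > 0:
            x += rng.normal(0.0, noise_sd, size=(C, n))
        segments.append(x)

    return Recording(
        subject=f"S{subject_index:02d}",
        condition=f"{config.stim_freq:.4g}Hz",
        fs=fs,
        channel_labels=labels,
        segments=segments,
    )


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[Recording], GroundTruth]:
    """Generate all subjects plus the planted ground truth.

    Identical ``config`` (including seed) yields bit-identical output.
    """
    recs = [generate_subject(config, s) for s in range(config.n_subjects)]
    labels = config.channel_labels
    edge_class: dict[tuple[str, str], str] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            edge_class[_norm_edge((labels[i], labels[j]))] = "null"
    for e in config.pos_edges:
        edge_class[_norm_edge(e)] = "positive"
    for e in config.neg_edges:
        edge_class[_norm_edge(e)] = "negative"
    truth = GroundTruth(
        entrain_factors=tuple(float(v) for v in config.gains()),
        edge_class=edge_class,
    )
    return recs, truth


def null_config(config: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """A copy of ``config`` with every coupling disabled and a trend-free null.

    Planted and background shared sources are removed and the dilution
    exponent is pinned to 1, so the stimulus-locked fraction of narrow-band
    power — and with it the expected coherence of every pair — is identical
    for all subjects.  Edge weights are then statistically independent of
    the entrainment gains (and hence of SNR), the reference condition for
    type-I-error calibration of the edge classification.  The broadband
    noise is lowered so its (gain-independent) contribution at the coherence
    bin cannot re-introduce a residual trend.
    """
    base = config if config is not None else GeneratorConfig()
    n = overrides.get("n_subjects", base.n_subjects)
    defaults = dict(
        pos_edges=(),
        neg_edges=(),
        background_coupling=0.0,
        # Constant entrainment and a gain-free dilution fraction: expected
        # coherence is identical for every subject.
        entrain_factors=tuple([1.0] * n),
        dilution_exponent=1.0,
        # Channel-gain spreads couple SNR and coherence through shared
        # structural noise even at fixed gain; a calibration null needs
        # them off.
        amplitude_spread=0.0,
        dilution_spread=0.0,
        # SNR still varies across subjects — through recording quality
        # (broadband noise level), which barely touches the narrow-band
        # coherence — so the edge screen sees a real SNR spread with no
        # coupled weights.  SNR scales with 1/noise_sd², so the reciprocal
        # square root makes the SNR levels evenly spaced (no leverage
        # points distorting the small-sample Pearson screen).
        noise_sd_per_subject=tuple(1.0 / np.sqrt(np.linspace(0.5, 2.0, n))),
    )
    defaults.update(overrides)
    return replace(base, **defaults)
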