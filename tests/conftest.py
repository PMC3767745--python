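import numpy as np
import pytest

from ssvepnet import CoherenceNetwork, GeneratorConfig, MONTAGE_18


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast 6-channel cohort configuration for integration tests."""
    labels = ("Fp1", "Fp2", "F3", "F4", "O1", "O2")
    return GeneratorConfig(
        n_subjects=5,
        n_channels=6,
        n_segments=3,
        channel_labels=labels,
        pos_edges=(("O1", "F3"),),
        neg_edges=(("O2", "F4"),),
        seed=7,
    )


def make_network(weights, labels=None, stim_freq=12.5):
    """Build a CoherenceNetwork from a dense symmetric matrix."""
    w = np.asarray(weights, dtype=float)
    if labels is None:
        labels = tuple(MONTAGE_18[: w.shape[0]])
    return CoherenceNetwork(
        node_labels=tuple(labels), weights=w, stim_freq=stim_freq
    )


def random_network(rng, n, p_edge=0.6, ensure_edge=True):
    """Random symmetric weighted network with weights in (0.05, 1)."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < p_edge
    if ensure_edge and not mask.any():
        mask[rng.integers(len(mask))] = True
    vals = rng.uniform(0.05, 1.0, size=len(iu[0])) * mask
    w[iu] = vals
    w = w + w.T
    return make_network(w, labels=[f"n{i}" for i in range(n)])
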