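"""Group sparsity search and top-edge thresholding (Network 0).

Coherence is never exactly zero, so whole-head networks are complete and
full of spurious weak edges.  The sparsity scan raises a cutoff in steps
of 0.01 until some subject's network would contain an isolated node; the
edge fraction surviving the preceding cutoff becomes the common sparsity,
and each network keeps that many of its strongest edges.
"""

import numpy as np

from ssvepnet import CoherenceNetwork, apply_sparsity, find_sparsity

rng = np.random.default_rng(4)
labels = tuple("ABCDEF")


def random_net(strength):
    w = np.triu(rng.uniform(0.1, strength, size=(6, 6)), k=1)
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return CoherenceNetwork(labels, w, stim_freq=12.5)


networks = [random_net(s) for s in (0.6, 0.8, 1.0)]
result = find_sparsity(networks, step=0.01)
print(f"first isolating cutoff: {result.critical_threshold:.2f}")
print(f"sparsity: {result.sparsity:.3f} "
      f"-> every network keeps its top {result.n_edges_kept} of 15 edges")

for k, net in enumerate(networks):
    net0 = apply_sparsity(net, result.sparsity)
    degrees = (net0.weights > 0).sum(axis=1)
    print(f"network {k}: kept {int((np.triu(net0.weights, 1) > 0).sum())} "
          f"edges, min degree {degrees.min()} (no isolated nodes)")
# All subjects end up with the same node and edge counts, which makes their
# topology metrics comparable, while each keeps its own strongest edges.
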