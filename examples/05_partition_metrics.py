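"""Partition Network 0 by SNR correlation and compute topology metrics.

Across subjects, each edge's strength is correlated with mean SNR; edges
significantly positive form Network 1, significantly negative Network 3,
the rest Network 2.  Weighted clustering, harmonic-mean path length, and
global/local efficiency are computed per subject for Networks 0, 1, 2.
"""

import numpy as np

from ssvepnet import (
    GeneratorConfig, apply_sparsity, classify_edges, compute_snr,
    edgewise_correlation, epochs_from_recording, find_sparsity,
    generate_cohort, network_metrics, recording_network, subnetwork,
)

config = GeneratorConfig(seed=0)
recordings, truth = generate_cohort(config)

networks = [recording_network(r, config.stim_freq) for r in recordings]
snrs = [compute_snr(epochs_from_recording(r), config.stim_freq).mean_snr
        for r in recordings]

sparsity = find_sparsity(networks)
nets0 = [apply_sparsity(n, sparsity.sparsity) for n in networks]

corr = edgewise_correlation(nets0, snrs)
part = classify_edges(corr, alpha=0.05)
print(f"edge classes over {len(corr.edges)} edges: "
      f"{len(part.edges_of('positive'))} positive, "
      f"{len(part.edges_of('nonsig'))} non-significant, "
      f"{len(part.edges_of('negative'))} negative")

recovered = [e for e in truth.planted("positive")
             if part.edge_class.get(tuple(sorted(e))) == "positive"]
print(f"planted positive edges recovered: {len(recovered)}/"
      f"{len(truth.planted('positive'))}")

weakest, strongest = int(np.argmin(snrs)), int(np.argmax(snrs))
for tag, s in (("lowest-SNR", weakest), ("highest-SNR", strongest)):
    net1 = subnetwork(nets0[s], part, "positive")
    tm = network_metrics(net1)
    print(f"{tag} subject, Network 1: clustering {tm.clustering:.3f}, "
          f"path length {tm.path_length:.3f}, global eff {tm.global_eff:.3f}, "
          f"local eff {tm.local_eff:.3f}")
# The strongly entrained subject's Network 1 is tighter: shorter harmonic-
# mean path length and larger efficiencies, the pattern the metric-SNR
# correlations quantify across the whole cohort.
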