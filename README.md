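# ssvepnet

Coherence-based functional brain-network analysis for steady-state visual
stimulation experiments.

When a subject views a light flickering at a fixed frequency above ~4 Hz,
the EEG entrains to it: the steady-state visually evoked potential (SSVEP)
is a near-sinusoidal response at the stimulus frequency and its harmonics.
Subjects differ widely in how strongly they entrain, and this package
implements an analysis chain that asks *why*: it relates each subject's
SSVEP strength to the topology of the functional network the stimulus
entrains.

The chain, for a cohort of subjects recorded under one or more flicker
frequencies `f0`:

1. **SNR.** Artifact-free segments are cut into 2.4 s epochs with 1.2 s
   overlap (an integer number of stimulus cycles fits each window).  The
   SSVEP response is `SNR = P(f0) / mean{P(f) : |f − f0| ≤ 0.5 Hz, f ≠ f0}`
   per channel, averaged over epochs and then over the 18-electrode
   montage.
2. **Connectivity.** Per epoch, the magnitude-squared coherence
   `w_xy = |C_xy(f0)|² / (C_xx(f0) C_yy(f0))` is estimated at the FFT bin
   nearest `f0` from 1.2 s Hann sub-windows; the 36–48 per-epoch 18×18
   matrices are averaged into the subject's whole-head network.
3. **Network 0.** A group sparsity value is found by raising a weight
   cutoff in steps of 0.01 until any subject's network would contain an
   isolated node; every network then keeps the corresponding number of its
   strongest edges.
4. **Partition.** Each edge's strength is Pearson-correlated with mean SNR
   across subjects; significantly positive edges (p < 0.05, uncorrected)
   form Network 1, significantly negative ones Network 3, the rest
   Network 2.
5. **Topology.** Weighted metrics per subject and network: Onnela
   clustering coefficient `C`, harmonic-mean characteristic path length
   `L = N(N−1) / Σ 1/L_ij` over edge lengths `1/w`, global efficiency
   `E_glob = 1/L`, and local efficiency (global efficiency of each node's
   neighbour subgraph).
6. **Statistics.** Metric–SNR Pearson correlations, and an edge-wise
   permutation test of nodal connectivity between the four highest- and
   four lowest-SNR subjects (exact enumeration over the 70 splits of
   4 + 4, or 5000 sampled re-partitions).

Because no public recordings accompany this design, the package ships a
first-class synthetic-cohort generator with planted ground truth: per-
subject entrainment gains drive both the stimulus-band SNR and the
coupling of designated long-range edges (positively or negatively), so the
whole chain can be validated end to end.  See `docs/methods.md` for the
signal model and its assumptions.

## Worked example

```python
from ssvepnet import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=0, out_dir="run0"))
table = result.correlations
net0 = table[(table.condition == "12.5Hz") & (table.network_id == 0)]
print(net0.to_string(index=False))
```

prints the Network-0 metric–SNR correlations of the default synthetic
cohort (11 subjects, 12.5 Hz flicker):

```
condition  network_id            metric         r        p  n
   12.5Hz           0 mean_connectivity  0.882519 0.000322 11
   12.5Hz           0        clustering  0.860556 0.000673 11
   12.5Hz           0       path_length -0.830630 0.001543 11
   12.5Hz           0        global_eff  0.882519 0.000322 11
   12.5Hz           0         local_eff  0.882519 0.000322 11
```

Subjects with stronger SSVEP responses have higher mean connectivity,
clustering and efficiencies, and a shorter characteristic path length —
their entrained networks are tighter and communicate more efficiently.
The run directory contains the SNR, metrics, correlation, partition and
permutation tables as CSV plus a JSON report; rerunning with the same seed
reproduces every file byte for byte.

The `examples/` directory walks through each stage separately
(`python examples/01_simulate_cohort.py`, …), and a thin CLI wraps the
pipeline (`ssvepnet simulate`, `ssvepnet analyze`, `ssvepnet report`).

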