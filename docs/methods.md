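# Methods

This note records the models, estimators, numerical choices and known
limitations behind `ssvepnet`.  The package analyses multichannel
recordings made under periodic visual stimulation and relates each
subject's steady-state response strength (SNR) to the topology of the
coherence network the stimulus entrains.

## Analysis chain

### Epochs and spectra

Segments (6 s by default) are cut into windows of 2.4 s with 1.2 s
overlap; starts fall on multiples of `window − overlap` and only fully
contained windows are kept, so a duration `T` yields
`floor((T − w)/(w − o)) + 1` epochs (a 6 s segment → 4 epochs; 9–12
segments → 36–48 epochs).  These lengths hold an integer number of cycles
of both default stimuli (12.5 Hz = 30 cycles, 16.67 Hz = 40 cycles per
2.4 s), so the stimulus frequency falls exactly on an FFT bin and a
rectangular window incurs zero leakage — no taper is used for SNR.
Spectra are scaled so that the one-sided bin powers sum to the mean square
of the signal (Parseval).

### SNR

Per channel and epoch, `SNR = P(f0) / mean{P(f): |f − f0| ≤ 0.5 Hz,
f ≠ f0}`; values are averaged over epochs, and the subject's response is
the mean over the montage's 18 channels.  At 2.4 s resolution
(0.4167 Hz/bin) the 1 Hz band discretizes to the two adjacent bins; the
band is configurable (`band_hz`) because this discretization is a choice,
not a law.  A zero noise-band power yields `inf` — reported, never
clipped.  Two properties of this ratio statistic worth knowing:

* it is invariant to global amplitude rescaling;
* for pure noise its *mean* is `k/(k−1)` for a `k`-bin band (bin powers
  are approximately iid exponentials), i.e. 2 at the default resolution —
  the folklore value 1 is the many-bin limit.  Tests assert the exact law.

### Coherence networks

Magnitude-squared coherence per epoch,
`w_xy = |Σ_k X_k Ȳ_k|² / (Σ_k |X_k|² Σ_k |Y_k|²)` over Welch sub-windows
`k`, is evaluated at the single bin nearest `f0` (the SSVEP is confined to
a very narrow band).  A single sub-window gives coherence ≡ 1, so each
2.4 s epoch uses 1.2 s Hann sub-windows with 50 % overlap (three per
epoch); 1.2 s still holds integer cycles of both stimuli.  Per-epoch
matrices are averaged into the subject's "original whole network".

The estimator is biased upward under independence: with `K` independent
sub-windows the null expectation is `1/K` (Beta(1, K−1)); with the
default three *overlapping* Hann sub-windows the effective floor is
≈ 0.45.  Averaging over epochs reduces the variance, not the bias, so all
network weights ride on this floor.  Tests verify the exact `1/K` law
with non-overlapping sub-windows and cross-check the full estimator
against an independent Welch implementation.

### Sparsity and Network 0

Because coherence is never zero, whole-head networks are complete.  The
group sparsity value scans cutoffs `t = 0, 0.01, …, 1`, deleting edges
with `w < t` in *every* network of *all* conditions; the first `t*` at
which any network contains an isolated node stops the scan, and the
sparsity is the largest per-network edge fraction surviving `t* − 0.01`.
Each network then keeps its `round(sparsity · N(N−1)/2)` strongest edges
(round-half-up; ties broken by weight descending, then lexicographic node
pair — determinism over elegance).  This "smallest common edge fraction
with no isolated nodes" interpretation implements the rule literally at
the isolated-node level; it does not check full graph connectivity, which
the stopping criterion's wording does not require.

### Partition into Networks 1/2/3

Subjects' Network-0 edge sets differ (top-edge selection is per subject),
so the edge universe is their union, a missing edge contributing weight 0.
Per edge, Pearson `r` between weight and mean SNR across subjects with a
two-sided `p` from the `t` transform (`n − 2` df), uncorrected.  Classes:
positive (`p < α`, `r > 0`) → Network 1; negative → Network 3; everything
else, including zero-variance edges (flagged), → Network 2.  The
classification is group-level: classes are identical across subjects,
weights are not.  Sub-network weight matrices sum to Network 0's per
subject (conservation).  Network 3 is typically too sparse for meaningful
topology and gets no metrics.

### Weighted topology metrics

* **Clustering** (Onnela): `C_i = Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
  (k_i(k_i−1))` with `ŵ = w / max(w)` over the network being measured,
  `C_i = 0` for degree < 2; the network value averages all N nodes.  Note
  this form is scale-invariant: only the weight *distribution* relative
  to the maximum matters.
* **Path length**: edge length `1/w`; all-pairs shortest paths by
  Dijkstra; `L = N(N−1)/Σ_{i≠j} 1/L_ij` (harmonic mean, `1/∞ = 0`), which
  stays finite under disconnection; an entirely edgeless network raises a
  signalled error (the pipeline records NaN).
* **Global efficiency**: `E_glob = mean 1/L_ij`; identically `1/L`, an
  identity asserted to machine precision.
* **Local efficiency**: global efficiency of the subgraph induced by each
  node's direct neighbours (node excluded, paths confined to the
  subgraph), 0 for degree < 2, averaged over all N nodes.

All four metrics are verified against brute-force enumeration (simple-path
enumeration, explicit triple loops) on hundreds of random graphs with ≤ 6
nodes to 1e−9.

### Group statistics

Metric–SNR relations use the same Pearson machinery (a constant metric —
e.g. clustering in a triangle-free sub-network — yields an NaN row rather
than aborting).  The high- vs low-SNR comparison takes the four highest-
and four lowest-SNR subjects and tests each union edge's difference of
mean weights by permutation: exact enumeration over all `C(8,4) = 70`
splits when feasible (auto-selected up to 10 000 splits), otherwise 5000
seeded re-partitions with the add-one estimator `(#extreme + 1)/(n + 1)`.
The tail follows the sign of the observed difference; consequently the
realized level of `p < 0.05` under the null is `2 × 3/70 ≈ 0.086`, not
0.05 — the procedure is reported as defined, and the calibration test
asserts the correct level.

## The synthetic cohort

No public recordings exist for this design, so validation uses a
generator whose defaults mirror the study conditions: 11 subjects,
18-channel 10–20 montage, 250 Hz sampling, 12 artifact-free 6 s segments
per condition, stimulus frequencies 12.5 and 16.67 Hz (80 ms and 60 ms
LED cycles).  Each channel superimposes:

* a **stimulus-locked tone** at `f0` (+ a 25 % second harmonic), amplitude
  `1.2 · g_s` with per-(channel, subject) lognormal spread (σ = 0.15) and
  a phase redrawn per segment.  `g_s` is the subject's entrainment gain
  (defaults `linspace(0.5, 2)`).  Being deterministic within a segment,
  the tone leaks nothing into the SNR noise band, so SNR grows
  monotonically with `g_s` against the broadband floor;
* a **narrow-band background** ("dilution") source per channel: a tone
  whose phase random-walks at 0.35 rad/sample (a few Hz of linewidth),
  decorrelating the coherence sub-windows.  Its amplitude
  `1.4 · g_s^{−0.5}` *shrinks* with entrainment, modelling event-related
  desynchronization of background rhythms near the stimulus frequency
  (for these stimuli, the alpha band).  Two consequences: the locked
  fraction of narrow-band power — and with it the coherence of *every*
  pair — drifts upward with `g_s` (the diffuse positive weight–SNR trend
  of the non-significant edge mass), and weight dispersion compresses in
  strongly entrained subjects (which is what makes the max-normalized
  clustering coefficient rise with SNR);
* **shared sources** on planted edges: mixing `1.5 · g_s²` on five
  positive edges and `6 / g_s` on two negative edges (long-range
  parieto-occipital–frontal and temporal–frontal pairs).  Since private
  locked power scales as `g_s²`, a shared weight ∝ `g_s` would leave
  coherence flat; the super-/sub-linear laws make edge strength genuinely
  rise or fall with entrainment.  The negative base is large so the shared
  power's decline beats the locked tone's rise at every default gain.
  Planted edges are node-disjoint: co-located shared sources dilute each
  other and flatten the planted trend;
* iid broadband Gaussian noise (sd 1.0; optionally per subject).

Effect sizes were fixed once from a design-space exploration targeting
high power at n = 11 (planted-edge recovery and the full metric sign
pattern hold across ten generator seeds); they are free parameters of the
generator, not quantities estimated from any dataset.

On these defaults the sparsity search returns 1.0: the coherence
estimator's bias floor keeps every weight above ≈ 0.35, so no node
isolates before the entire network does.  The sparsity stage is therefore
validated on constructed network collections where the scan has a
non-trivial answer.

### The calibration null

Type-I calibration of the edge screen uses `null_config()`: no planted or
background coupling, constant gains, dilution exponent 1 (locked fraction
— hence expected coherence — identical for all subjects), channel-gain
spreads off, and SNR varied through per-subject broadband noise levels
chosen so the SNR spread is evenly spaced.  One further design point
matters: when SNR and networks are estimated from the *same* epochs their
estimation noises are correlated, which genuinely inflates the screen's
false-positive rate (to ≈ 0.054–0.064 at n = 11 in our measurements) even
when the underlying quantities are independent.  The calibration
experiment therefore estimates SNR and networks from disjoint halves of
each recording's segments; the measured rate is then ≈ 0.052, within the
binomial band of α = 0.05, the remaining sliver being the Pearson
t-approximation's small-sample liberality on bounded weights.  The
full-pipeline coupling is a limitation shared by any study that screens
edges against an SNR computed from the same data.

## What the synthetic validation does and does not show

Passing tests demonstrate that the chain recovers planted monotone
weight–SNR structure, that its estimators obey their sampling laws, and
that its graph metrics are exactly the stated functions of the weights.
They do not show that real EEG satisfies the generator's assumptions: no
volume conduction or shared-reference effects (which inflate short-range
coherence), no 1/f background or artifacts, no harmonically rich or
non-stationary responses, and between-subject variation reduced to a
single gain plus lognormal channel factors.  Real-data peculiarities such
as the choice of reference, electrode dropout, or non-monotone
SNR–topology relations are out of scope.

## Problem sizes and tolerances

Default validation sizes: 500 random graphs (≤ 6 nodes) for metric-oracle
equivalence at 1e−9 and 200 for the `E·L = 1` identity; 2000 replicates
for the coherence null bias (3 SE band); 200 null cohorts (10 channels,
6 segments, 11 subjects) for the false-positive rate; the full default
cohort for recovery and sign patterns; 5000 sampled permutations against
exact enumeration (agreement within 0.02 on the planted edges).  These
sizes give stable Monte-Carlo error while keeping the whole suite fast;
all randomness is seeded and reruns are bit-identical.
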