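# Methods

This note documents the models, estimators and numerical conventions
implemented in `afnet`, the choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Problem setting

During persistent atrial fibrillation (AF) there is no consistent
activation pattern on a time scale of seconds, so directed measures of
propagation are ill-posed.  The analysis instead treats the atria as a
*communication network*: nodes are the cardiac tissue patches adjacent
to each electrode of a 64-pole basket catheter (8 splines × 8
electrodes), and an edge between two nodes exists when their
electrograms share sufficient information.  Pairwise information
sharing is quantified with mutual information (in nats), the networks
are binarized at fixed *connection density* (fraction of strongest
pairs kept), and each network is summarized by six parameters whose
clustering/path-length components are normalized against matched random
graphs.  Conditions (e.g. pre vs post ablation) are compared with
paired nonparametric tests on the density-resolved parameter curves.

## Preprocessing

**Far-field removal.**  Unipolar atrial electrograms carry a
ventricular QRS-T deflection at every beat.  R peaks are detected on a
simultaneous surface-ECG reference (5–25 Hz zero-phase band-pass,
absolute envelope, adaptive threshold at 0.5 × the 2-s rolling maximum,
250 ms refractory period keeping the larger of competing peaks).  Beat
positions are then refined by least-squares template matching on the
ECG: envelope detection is accurate only to a sample or two, and a
one-sample misalignment of a sharp QRS leaves a visible subtraction
artifact.  The mean QRS-T complex (default span 50 ms before to 400 ms
after the R peak; the span is configurable) is computed across all
beats that lie fully inside the record, and subtracted at every beat
from every basket channel.  The subtraction scale is a per-channel
least-squares fit: far-field amplitude varies strongly across basket
electrodes but is nearly constant across beats at one electrode, so the
default pools the per-beat fits into one median scale per channel —
per-beat scales are supported but let atrial signal inside the beat
window leak into each scale estimate.  Samples outside beat windows are
bit-identical to the input.  On synthetic recordings with known ground
truth the full chain leaves a residual below 5% of the atrial RMS.

**Windowing.**  Recordings are cut into consecutive, non-overlapping
windows — by default the first 5 windows of 10 s, discarding any
remainder of a 60-s recording.  Ten seconds is two orders of magnitude
above the AF cycle length (120–240 ms), long enough for stable
probability estimates and short enough to tolerate slow drift.

## Mutual information (KSG estimator)

For each channel pair and window, mutual information is estimated with
the Kraskov–Stögbauer–Grassberger k-nearest-neighbor estimator in its
rectangle (algorithm-2) form:

    I(X;Y) = ψ(k) − 1/k − ⟨ψ(n_x(i)) + ψ(n_y(i))⟩ + ψ(N)

where the k-th nearest neighbor of each joint sample is found under the
max norm, ε_x(i)/2 and ε_y(i)/2 are the marginal projections of that
neighborhood, and n_x(i), n_y(i) count points within or on the boundary
of each marginal slab (|x_i − x_j| ≤ ε_x(i)/2).  Conventions:

- **k = 4**, following the original estimator analysis; configurable.
- **Digamma** of integer arguments uses ψ(n) = −γ + Σ_{j=1}^{n−1} 1/j.
- **Tie-breaking**: the estimator assumes continuous data; repeated
  values corrupt the counts.  A deterministic jitter of 1e-10 × the
  series SD is added before the neighbor search.  The jitter seed is
  derived from the series content plus the configured seed, which makes
  the estimate exactly symmetric in its arguments and bit-reproducible.
- **Boundary robustness**: marginal counts use binary search on the
  sorted marginals with the radius widened by one part in 1e12, so the
  neighbor defining the boundary cannot be lost to floating-point
  rounding; counts are floored at 1.
- **Negative estimates** (small-sample fluctuation around zero for
  independent pairs) are reported unclipped — clipping would bias the
  edge ranking near zero, exactly where density thresholds cut.
- Inputs are the preprocessed voltages as-is; no per-window
  normalization by default (the estimator is invariant under monotone
  marginal transformations in the large-N limit), a z-scoring flag
  exists for exploration.

Per window, all n(n−1)/2 pairs are estimated (the per-channel jitter
and sorted marginals are shared across pairs); the per-window matrices
are averaged elementwise into the matrix used downstream.  Accuracy on
bivariate Gaussians (N = 10,000): within ±0.02 nats of
−½ln(1−ρ²) for ρ ∈ {0, 0.5, 0.9} in the 20-seed mean.  A 64-channel ×
9,770-sample window takes well under a minute per window on one CPU
(KD-tree joint queries plus sorted-marginal range counts).

## Communication networks

**Thresholding.**  Pairs are ranked by averaged MI descending; the top
round(d · n(n−1)/2) become edges (half-up rounding; the paper's
rounding convention is not stated).  Ties at the cut break by ascending
(row, column) index for cross-platform reproducibility.  The smallest
kept value is recorded as the threshold.  Self-edges are excluded; a
density that keeps zero edges yields a valid empty network with a
warning.

**The six parameters.**  Number of edges; average degree (2m/n); giant
component (nodes in the largest connected component; an isolated node
counts as size 1); average clustering coefficient (triangle counts via
A³; nodes with degree < 2 contribute 0 — a convention the underlying
definition leaves open); characteristic path length (mean BFS geodesic
over *reachable* pairs, excluding pairs split across components —
disconnection is certain at density 0.1 and the alternative conventions
are either undefined or need an arbitrary penalty; giant-component-only
averaging is available behind a flag); and the small-world index
σ = C_norm / L_norm.

**Null model.**  "Random networks with the same number of degrees and
edges" is implemented as G(n, m): uniform random graphs with exactly
the empirical node and edge counts (and hence the same average degree).
Degree-sequence-preserving rewiring is deliberately *not* used.  Each
normalization uses an ensemble (default 100 graphs, seeded) whose C and
L are computed with the identical conventions as the empirical network;
C_norm = C/⟨C_rand⟩, L_norm = L/⟨L_rand⟩.  σ is additionally expressed
as a z-score against the ensemble's own σ distribution (the choice of
reference population for the z-score is a declared convention of this
package).  Ensembles are cached by (n, m), so all subjects at one
density share one normalization reference.

Calibration: graphs drawn from the null itself give C_norm and L_norm
within 3 relative ensemble SDs of 1 and |z| ≤ 3 in ≥95% of draws;
Watts–Strogatz graphs (n = 64, k = 6, p = 0.05) are detected as
small-world (σ > 1, z > 2) in ≥90% of seeds.

## Group statistics

Subject-level curves (metric vs density) are compared with a Wilcoxon
signed-rank test: exact null distribution for n ≤ 25 pairs (dynamic
programming over rank sums, equivalent to full 2^n sign-flip
enumeration; zero differences dropped, average ranks for ties),
tie-corrected normal approximation above.  Tests run per density point
and — the headline number — pooled on each subject's density-averaged
metric; the aggregation across the density grid is this package's
convention, chosen because a single p-value per panel is reported.
Group summaries are means with t-distribution 95% CIs.  No
multiple-testing correction by default (matching the reporting style);
Benjamini–Hochberg is available behind a flag.

## Synthetic-data generator

No patient recordings are available, so the generator produces the
study conditions the pipeline is tested under:

- **Signals**: each channel fires biphasic derivative-of-Gaussian
  deflections (width 10–20 ms, drawn per channel) on a quasi-periodic
  activation train: per-train base cycle length uniform in 120–240 ms
  (the AF range), Gaussian timing jitter of 5 ms SD per event, event
  amplitudes N(1, 0.1²), plus white amplitude noise (default SD 0.1 of
  the unit deflection — no amplitude/SNR statistics are published for
  basket electrograms, so SNR ≈ 10 is a declared free parameter).
  Defaults: 977 Hz, 60 s, 64 channels.
- **Coupling**: each planted edge owns a shared latent activation
  train.  A fraction c (the edge's coupling strength) of that train's
  events is selected *once per edge*, and both endpoint channels fire
  at exactly those times (plus their own jitter); the remaining
  1 − Σc fraction of a node's events come from its private train,
  thinned to keep the activation rate constant.  Linked channels
  therefore share a fraction c of activation times; at c = 1 their
  trains are identical up to noise, at c = 0 independent, and measured
  MI is monotone in c.  A node's total incident coupling is capped at 1
  (it cannot share more than all of its events); topologies in the
  experiments respect this budget by construction.  A convex
  combination of event *times* — the seemingly simpler reading — was
  rejected: private trains with different base cycles drift apart
  linearly in event index, so for c < 1 the shared component produces
  no temporal alignment and planted edges carry no excess MI.
  Per-edge (rather than per-connected-component) drivers keep MI
  specific to planted edges: a single component-wide driver would make
  indirect neighbors as informative as direct ones.
- **Truth topologies**: ring lattice, Watts–Strogatz, G(n, m), random
  matching (disjoint pairs — transitivity-free, used for planted-edge
  recovery checks), disjoint chains, and "clustered" (disjoint
  triangles joined by random bridges, with separate triangle/bridge
  couplings chosen to exhaust the per-node budget).
- **Ventricular far field**: a synthetic QRS-T waveform (sharp biphasic
  QRS plus a slow T bump, 50 + 400 ms span) is added at quasi-regular R
  times (default RR 750 ms, 20 ms jitter), scaled per channel
  (log-normal spread around amplitude 1.5); the same waveform at unit
  amplitude plus light noise forms the surface-ECG reference.  Beats
  are placed only where the full span fits inside the record.

What the generator does **not** emulate: biophysical tissue dynamics
(no monodomain/ionic models, no rotors or wavefront geometry), spatial
correlation between neighboring electrodes, electrode contact loss or
motion artifact, baseline wander, or any 3-D geometry beyond the label
layout.  Passing tests therefore demonstrate that the *pipeline*
recovers planted information-sharing structure under realistic signal
statistics — not that the biological conclusions about AF transfer.

## Synthetic ablation experiment

The paired-cohort experiment mirrors the clinical contrast at desk
scale.  The coupling substrate changes between conditions:

- *Baseline* — unclustered, geodesically long information sharing: a
  bare coupling ring at strength 0.5 (exhausting the per-node sharing
  budget at degree 2).  Its thresholded networks are triangle-poor
  chains and loops that fragment at low density.
- *Post-ablation* — locally clustered coupling with global shortcuts:
  disjoint triangles (coupling 0.3) joined by 7 random bridges
  (coupling 0.4), again saturating the corner budget.  Thresholded
  networks gain closed triangles (C_norm up) and shortcuts (L_norm
  down), raising σ.

Each subject draws its own substrate (topology seed), shared across
its two conditions, and a fresh signal realization per condition — the
natural reading of a paired cohort.  A `shared_topology` option forces
one common substrate motif across subjects, which removes substrate
heterogeneity from the variance but makes the planted effect size
hostage to a single topology draw; it is off by default.  Cohorts are
compared with the pooled paired Wilcoxon test per metric.  Null
cohorts (both conditions from the same substrate, fresh signal noise)
control the type-I rate at the nominal level.

Problem sizes are scaled for a single CPU: 15-channel baskets, 30-s
recordings cut into 3 × 10-s windows, a five-point density grid
(0.10–0.30), 20 subjects, 100-graph null ensembles.  These sizes are
stated in `afnet.pipeline.EXPERIMENT_DEFAULTS` and were chosen so the
full experiment runs in minutes while each window still gives the KSG
estimator ~10⁴ samples.

A caveat on the giant component: with per-edge couplings bounded by
the node budget (strength ≤ 1/degree), the detectable planted skeleton
can never have average degree much above 2, and proportional-density
thresholding fills all remaining edge slots with uniformly random
noise pairs, which percolate: by density ≈ 0.15–0.2 every measured
network connects regardless of the planted topology.  Pooled over the
0.10–0.30 grid the giant component therefore differs between
conditions by well under one node, and its paired comparison is not
expected to reach significance at this scale — unlike clustering, path
length and σ, whose contrasts are carried by *which* pairs are kept
rather than by percolation.

## Numerical and reproducibility conventions

- Every random stage derives its seed from the global seed plus stage
  tokens via SHA-256 (`afnet._seeds.derive_seed`), so runs are
  bit-identical across platforms and any stage can be regenerated in
  isolation.
- Degenerate inputs: constant series warn and estimate on tie-break
  noise; empty networks are valid objects; path length without edges,
  normalization with a zero-mean null, and all-zero Wilcoxon
  differences raise typed errors.
- MI matrices are exactly symmetric with a forced-zero diagonal; all
  entries finite.

## Known limitations

- The estimator treats samples as i.i.d.; electrogram autocorrelation
  inflates the effective variance of MI estimates (windowed averaging
  mitigates but does not remove this).  Absolute MI values should be
  read as rankings, not information rates.
- G(n, m) normalization ignores the degree sequence; clustered
  empirical networks with hubs would normalize differently under a
  configuration-model null.
- The per-node coupling budget bounds how strongly a high-degree node
  can couple to all its neighbors, which in turn bounds the contrast
  achievable in dense planted topologies.
- Reachable-pairs path length deflates L for highly fragmented
  networks; cross-density comparisons of L should be read jointly with
  the giant-component curve.
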