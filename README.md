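# afnet

Communication-network analysis of multichannel atrial-fibrillation
electrograms: QRS-T far-field removal, windowed Kraskov k-nearest-neighbor
mutual information between all electrode pairs, density-thresholded binary
networks, and small-world metrics normalized by matched random-graph null
ensembles, with paired nonparametric comparison between conditions.

## Who this is for

Researchers analyzing multi-electrode intracardiac recordings (e.g.
64-pole basket catheters) who want to quantify *functional connectivity*
during fibrillation — where activation has no consistent direction and
propagation-based measures fail — and to compare network organization
across conditions such as pre/post ablation.  Because clinical recordings
are rarely shareable, the package ships a synthetic-data generator that
plants a known coupling network in AF-like electrograms, so the whole
chain is testable end to end against ground truth.

## The method

For channels X, Y in a 10-s window, mutual information (nats) is estimated
with the KSG k-nearest-neighbor estimator (rectangle variant, k = 4):

    Î(X;Y) = ψ(k) − 1/k − ⟨ψ(n_x(i)) + ψ(n_y(i))⟩ + ψ(N)

where ε_x(i)/2, ε_y(i)/2 are the marginal projections of the distance to
the k-th joint neighbor (max norm) and n_x(i), n_y(i) the
boundary-inclusive marginal neighbor counts.  The 64×64 matrices of all
2,016 channel pairs are averaged over 5 consecutive windows, then
binarized at connection densities 0.10–0.30 (top fraction of strongest
pairs).  Each network is summarized by: number of edges, average degree,
giant component, average clustering coefficient C, characteristic path
length L, and the small-world index σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩), with
⟨·_rand⟩ from a G(n, m) ensemble matched on nodes and edges and σ also
expressed as a z-score against the ensemble.  Conditions are compared
per metric with Wilcoxon signed-rank tests (exact for n ≤ 25 pairs),
pooled over the density grid.

See `docs/methods.md` for conventions, parameter defaults, and what the
synthetic generator does and does not emulate.

## Worked example

```python
import numpy as np
from afnet import (
    KSGParameters, SimulationConfig, generate_basket_layout,
    generate_planted_network, simulate_coupled_af, segment_windows,
    windowed_average_mi, density_sweep, NullEnsembleCache,
)

layout = generate_basket_layout(4, 4)              # 16-channel basket
truth = generate_planted_network(16, "matching", coupling=0.6, seed=3)
rec = simulate_coupled_af(layout, truth, SimulationConfig(duration_s=50.0, seed=3))
windows = segment_windows(rec, window_s=10.0, n_windows=5)
averaged, _ = windowed_average_mi(windows, KSGParameters(seed=3), rec.labels)

iu = np.triu_indices(16, 1)
planted = truth.adjacency[iu].astype(bool)
vals = averaged.values[iu]
print(f"planted pairs:     {vals[planted].mean():.4f} nats")
print(f"non-planted pairs: {vals[~planted].mean():.4f} nats")
```

prints

```
planted pairs:     0.0349 nats
non-planted pairs: 0.0012 nats
```

The eight planted channel pairs (coupling 0.6) carry an order of
magnitude more shared information than the 112 unlinked pairs, so they
dominate the edge ranking that density thresholding keeps.  Longer
narrative examples — far-field subtraction with known ground truth,
density sweeps with null-normalized metrics, and the paired synthetic
ablation experiment — live in `examples/` (each runs in seconds to a
few minutes and prints what its numbers mean).

There is also a thin CLI for end-to-end runs:

```bash
afnet simulate --seed 1 --out rec.tsv --splines 4 --per-spline 4
afnet preprocess rec.tsv --out clean.tsv
afnet mi clean.tsv --out mi.tsv
afnet network mi.tsv --out metrics.csv
afnet run --config config.yaml        # full pipeline with manifest
```

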