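"""Density-thresholded communication networks and small-world metrics.

The averaged mutual-information matrix is binarized by *connection
density*: the top ``round(d * n(n-1)/2)`` strongest channel pairs become
undirected edges (self-edges excluded).  Six parameters summarize each
network — edge count, average degree, giant-component size, average
clustering coefficient, characteristic path length, and the small-world
index sigma — with clustering and path length normalized by a G(n, m)
random-graph ensemble matched on node and edge counts, and sigma
additionally expressed as a z-score against the ensemble's own sigma
distribution.

Clustering is computed from the adjacency matrix (triangle counts via
A^3) and geodesic distances with breadth-first search through
``scipy.sparse.csgraph``; both are cross-checked against networkx and
brute-force enumeration in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .ksg import MIMatrix


class UndefinedMetricError(ValueError):
    """Metric undefined for this graph (e.g. path length with no edges)."""


class UndefinedNormalizationError(ValueError):
    """Null-ensemble mean is zero; normalized metric undefined."""


@dataclass
class CommunicationNetwork:
    """Binary undirected network at a given connection density."""

    adjacency: np.ndarray
    density: float
    threshold_value: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-edges are not allowed")
        self.adjacency = a.astype(int)
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(a.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def _adj(net) -> np.ndarray:
    return net.adjacency if hasattr(net, "adjacency") else np.asarray(net)


# --------------------------------------------------------------------------
# thresholding


def threshold_by_density(mi: MIMatrix, density: float) -> CommunicationNetwork:
    """Keep the top ``round(density * n(n-1)/2)`` strongest pairs as edges.

    Pairs are ranked by MI descending; ties at the cut are broken by
    ascending (row, column) index so results are reproducible.  Rounding
    is half-up.  The smallest kept MI value is recorded as the
    threshold; an empty network (density so low that zero edges survive)
    is returned valid with a warning.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = mi.n_channels
    rows, cols = np.triu_indices(n, k=1)
    vals = mi.values[rows, cols]
    total = len(vals)
    m = int(np.floor(density * total + 0.5))  # half-up
    order = np.lexsort((cols, rows, -vals))
    keep = order[:m]
    adj = np.zeros((n, n), dtype=int)
    adj[rows[keep], cols[keep]] = 1
    adj |= adj.T
    if m == 0:
        warnings.warn("density keeps zero edges; empty network", stacklevel=2)
        thr = float("nan")
    else:
        thr = float(vals[keep].min())
    return CommunicationNetwork(adj, float(density), thr, list(mi.labels))


# --------------------------------------------------------------------------
# the six parameters


def count_edges(net) -> int:
    """Total number of edges: half the adjacency sum."""
    return int(_adj(net).sum() // 2)


def average_degree(net) -> float:
    """Average number of edges per node: 2m / n."""
    a = _adj(net)
    return 2.0 * count_edges(a) / a.shape[0]


def giant_component_size(net) -> int:
    """Node count of the largest connected component (>= 1)."""
    a = _adj(net)
    n_comp, membership = connected_components(csr_matrix(a), directed=False)
    return int(np.bincount(membership, minlength=1).max())


def average_clustering(net) -> float:
    """Mean local clustering coefficient over all nodes.

    The local coefficient of node v is (closed triangles at v) /
    (deg(v) choose 2); nodes with degree < 2 contribute 0.
    """
    a = _adj(net).astype(float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    local = np.divide(triangles, possible, out=np.zeros_like(possible),
                      where=possible > 0)
    return float(local.mean())


def characteristic_path_length(net, *, mode: str = "reachable") -> float:
    """Mean geodesic (BFS hop) distance between node pairs.

    ``mode="reachable"`` (default) averages over all reachable pairs,
    excluding pairs split across components; ``mode="giant"`` restricts
    to pairs inside the giant component.  Raises if the graph has no
    edges (no pair is reachable).
    """
    a = _adj(net)
    if a.sum() == 0:
        raise UndefinedMetricError("characteristic path length needs >= 1 edge")
    if mode == "giant":
        _, membership = connected_components(csr_matrix(a), directed=False)
        giant = np.argmax(np.bincount(membership))
        idx = np.flatnonzero(membership == giant)
        a = a[np.ix_(idx, idx)]
    elif mode != "reachable":
        raise ValueError("mode must be 'reachable' or 'giant'")
    d = shortest_path(csr_matrix(a), method="D", directed=False, unweighted=True)
    iu = np.triu_indices(a.shape[0], k=1)
    dist = d[iu]
    finite = dist[np.isfinite(dist)]
    if len(finite) == 0:
        raise UndefinedMetricError("no reachable node pairs")
    return float(finite.mean())


# --------------------------------------------------------------------------
# null-model normalization


@dataclass
class NullEnsemble:
    """G(n, m) random-graph ensemble summary for normalization.

    Uniform random graphs with exactly the empirical node and edge
    counts; clustering and path length are computed with the identical
    conventions as the empirical pipeline, and the per-graph sigma
    distribution supports the small-world z-score.
    """

    n_nodes: int
    n_edges: int
    ensemble_size: int
    seed: int
    mean_C_rand: float
    sd_C_rand: float
    mean_L_rand: float
    sd_L_rand: float
    sigma_rand_values: np.ndarray


def _gnm_adjacency(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    rows, cols = np.triu_indices(n, k=1)
    pick = rng.choice(len(rows), size=m, replace=False)
    a = np.zeros((n, n), dtype=int)
    a[rows[pick], cols[pick]] = 1
    return a | a.T


def build_null_ensemble(
    n_nodes: int,
    n_edges: int,
    ensemble_size: int = 100,
    seed: int = 0,
    *,
    path_mode: str = "reachable",
) -> NullEnsemble:
    """Draw a G(n, m) ensemble and summarize its C, L and sigma."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must lie in [0, {max_edges}]")
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(ensemble_size):
        a = _gnm_adjacency(n_nodes, n_edges, rng)
        cs.append(average_clustering(a))
        if n_edges > 0:
            ls.append(characteristic_path_length(a, mode=path_mode))
    cs = np.array(cs)
    ls = np.array(ls) if ls else np.array([np.nan])
    mean_c, mean_l = float(cs.mean()), float(ls.mean())
    if mean_c > 0 and mean_l > 0:
        sigmas = (cs / mean_c) / (ls / mean_l)
    else:
        sigmas = np.full(len(cs), np.nan)
    return NullEnsemble(
        n_nodes=n_nodes,
        n_edges=n_edges,
        ensemble_size=ensemble_size,
        seed=seed,
        mean_C_rand=mean_c,
        sd_C_rand=float(cs.std(ddof=1)) if len(cs) > 1 else 0.0,
        mean_L_rand=mean_l,
        sd_L_rand=float(ls.std(ddof=1)) if len(ls) > 1 else 0.0,
        sigma_rand_values=sigmas,
    )


def normalized_metrics(net, null: NullEnsemble) -> tuple[float, float]:
    """(C_norm, L_norm): empirical C and L divided by the null means."""
    a = _adj(net)
    if a.shape[0] != null.n_nodes or count_edges(a) != null.n_edges:
        raise ValueError("null ensemble not matched on node/edge counts")
    if null.mean_C_rand == 0:
        raise UndefinedNormalizationError("null mean clustering is zero")
    c_norm = average_clustering(a) / null.mean_C_rand
    l_norm = characteristic_path_length(a) / null.mean_L_rand
    return float(c_norm), float(l_norm)


def small_world_index(net, null: NullEnsemble) -> tuple[float, float]:
    """Small-world index sigma = C_norm / L_norm, plus its ensemble z-score.

    The z-score positions the empirical sigma within the null ensemble's
    own sigma distribution; it is NaN (with a warning) when that
    distribution has zero spread.
    """
    c_norm, l_norm = normalized_metrics(net, null)
    if l_norm <= 0:
        raise UndefinedMetricError("L_norm must be positive for sigma")
    sigma = c_norm / l_norm
    sd = float(np.std(null.sigma_rand_values, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("null sigma spread is zero; z undefined", stacklevel=2)
        return float(sigma), float("nan")
    z = (sigma - float(np.mean(null.sigma_rand_values))) / sd
    return float(sigma), float(z)


# --------------------------------------------------------------------------
# combined metric set and density sweep


@dataclass
class NetworkMetrics:
    """The six communication-network parameters for one network."""

    density: float
    n_edges: int
    avg_degree: float
    giant_component: int
    avg_clustering: float
    C_norm: float
    char_path_length: float
    L_norm: float
    small_world_sigma: float
    small_world_z: float

    def as_dict(self) -> dict[str, float]:
        return {
            "density": self.density,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "giant_component": self.giant_component,
            "avg_clustering": self.avg_clustering,
            "C_norm": self.C_norm,
            "char_path_length": self.char_path_length,
            "L_norm": self.L_norm,
            "small_world_sigma": self.small_world_sigma,
            "small_world_z": self.small_world_z,
        }


def compute_metrics(net: CommunicationNetwork, null: NullEnsemble) -> NetworkMetrics:
    """All six parameters of one network against a matched null."""
    c_norm, l_norm = normalized_metrics(net, null)
    sigma, z = small_world_index(net, null)
    return NetworkMetrics(
        density=net.density,
        n_edges=count_edges(net),
        avg_degree=average_degree(net),
        giant_component=giant_component_size(net),
        avg_clustering=average_clustering(net),
        C_norm=c_norm,
        char_path_length=characteristic_path_length(net),
        L_norm=l_norm,
        small_world_sigma=sigma,
        small_world_z=z,
    )


DEFAULT_DENSITY_GRID = tuple(np.round(np.arange(0.10, 0.301, 0.01), 2))


class NullEnsembleCache:
    """Share G(n, m) ensembles across recordings of equal size.

    Every recording thresholded to the same (n_nodes, n_edges) uses the
    same ensemble, which both saves time and puts all subjects on a
    common normalization reference.
    """

    def __init__(self, ensemble_size: int = 100, seed: int = 0):
        self.ensemble_size = ensemble_size
        self.seed = seed
        self._store: dict[tuple[int, int], NullEnsemble] = {}

    def get(self, n_nodes: int, n_edges: int) -> NullEnsemble:
        key = (n_nodes, n_edges)
        if key not in self._store:
            self._store[key] = build_null_ensemble(
                n_nodes, n_edges, self.ensemble_size, self.seed
            )
        return self._store[key]


def density_sweep(
    mi: MIMatrix,
    densities=DEFAULT_DENSITY_GRID,
    *,
    null_cache: NullEnsembleCache | None = None,
) -> list[tuple[float, NetworkMetrics | None]]:
    """Full metric set at each density on a shared null-ensemble policy.

    Per-density failures (e.g. an empty network at very low density) are
    recorded as ``None`` with a warning instead of aborting the sweep.
    """
    if any(not 0 < d <= 1 for d in densities):
        raise ValueError("densities must lie in (0, 1]")
    cache = null_cache or NullEnsembleCache()
    out: list[tuple[float, NetworkMetrics | None]] = []
    for d in densities:
        try:
            net = threshold_by_density(mi, d)
            null = cache.get(net.n_nodes, count_edges(net))
            out.append((float(d), compute_metrics(net, null)))
        except (UndefinedMetricError, UndefinedNormalizationError) as exc:
            warnings.warn(f"density {d}: {exc}", stacklevel=2)
            out.append((float(d), None))
    return out
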