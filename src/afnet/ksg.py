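"""Kraskov-Stoegbauer-Grassberger k-nearest-neighbor mutual information.

Implements the rectangle (algorithm-2) variant of the KSG estimator for
a pair of continuous time series X, Y:

    I(X;Y) = psi(k) - 1/k - < psi(n_x(i)) + psi(n_y(i)) > + psi(N)

where, for each joint sample z_i = (x_i, y_i), the k-th nearest joint
neighbor is found under the max norm, eps_x(i) and eps_y(i) are the
marginal projections of that neighborhood (eps_x(i)/2 is the largest
|x_i - x_j| among the k joint neighbors), and n_x(i), n_y(i) count the
points lying within or on the boundary of each marginal slab,
||x_i - x_j|| <= eps_x(i)/2.  Estimates are in nats and may be slightly
negative for independent data; they are returned unclipped.

Repeated values violate the estimator's continuity assumption, so a tiny
deterministic jitter (1e-10 x the series SD by default) is added before
the neighbor search.  The jitter seed is derived from the series content
as well as the configured seed, which makes the estimate exactly
symmetric in its arguments.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

EULER_GAMMA = 0.5772156649015328606


def digamma_int(n: int) -> float:
    """Digamma at a positive integer: psi(n) = -gamma + sum_{j=1}^{n-1} 1/j."""
    if n < 1 or int(n) != n:
        raise ValueError("digamma_int requires a positive integer")
    n = int(n)
    if n > 10_000:  # same identity, evaluated without the explicit sum
        return float(digamma(n))
    return float(-EULER_GAMMA + np.sum(1.0 / np.arange(1, n)))


@dataclass
class KSGParameters:
    """Estimator settings: neighbor order k, tie-break jitter, seed."""

    k: int = 4
    tie_noise_scale: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class MIMatrix:
    """Symmetric channels x channels mutual-information matrix in nats.

    The diagonal is identically zero: self-edges are excluded from the
    communication network, so I(X;X) is never reported.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    tag: str | int = "window"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("MI matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("MI matrix contains non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("MI matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(v.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle entries, one per unordered channel pair."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


def _jitter(x: np.ndarray, scale: float, seed: int) -> np.ndarray:
    """Deterministic tie-break jitter seeded by content + configured seed.

    Content-derived seeding keeps pairwise estimates exactly symmetric
    (swapping the arguments produces the same two jittered series).
    """
    x = np.asarray(x, dtype=float)
    h = hashlib.sha256(np.int64(seed).tobytes() + np.ascontiguousarray(x).tobytes())
    sub = int.from_bytes(h.digest()[:4], "big")
    rng = np.random.default_rng(sub)
    sd = float(np.std(x))
    amp = scale * (sd if sd > 0 else 1.0)
    return x + rng.normal(0.0, amp, size=x.shape)


def _marginal_counts(sorted_vals: np.ndarray, vals: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boundary-inclusive neighbor counts per point, excluding the point.

    Counts j with |v_i - v_j| <= r_i via binary search on the sorted
    marginal.  The radius is widened by one part in 1e12 so the neighbor
    that defines the boundary survives floating-point rounding; counts
    are floored at 1 (that defining neighbor always exists).
    """
    r = radii * (1.0 + 1e-12)
    hi = np.searchsorted(sorted_vals, vals + r, side="right")
    lo = np.searchsorted(sorted_vals, vals - r, side="left")
    return np.maximum(hi - lo - 1, 1)


def _ksg_core(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    psi_table: np.ndarray,
    xs: np.ndarray | None = None,
    ys: np.ndarray | None = None,
) -> float:
    """KSG algorithm-2 estimate on pre-jittered series."""
    n = len(x)
    z = np.column_stack((x, y))
    tree = cKDTree(z)
    _, idx = tree.query(z, k=k + 1, p=np.inf)
    nbrs = idx[:, 1:]
    r_x = np.abs(x[nbrs] - x[:, None]).max(axis=1)
    r_y = np.abs(y[nbrs] - y[:, None]).max(axis=1)
    if xs is None:
        xs = np.sort(x)
    if ys is None:
        ys = np.sort(y)
    n_x = _marginal_counts(xs, x, r_x)
    n_y = _marginal_counts(ys, y, r_y)
    return float(
        psi_table[k] - 1.0 / k - np.mean(psi_table[n_x] + psi_table[n_y]) + psi_table[n]
    )


def _psi_table(n: int) -> np.ndarray:
    t = digamma(np.arange(1, n + 1, dtype=float))
    return np.concatenate(([np.nan], t))  # index by integer count directly


def ksg_mutual_information(
    x: np.ndarray, y: np.ndarray, params: KSGParameters | None = None
) -> float:
    """Estimate I(X;Y) in nats for two equal-length series.

    May return slightly negative values for independent data; the
    estimate is not clipped (clipping would bias edge ranking near 0).
    """
    params = params or KSGParameters()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if n <= params.k:
        raise ValueError(f"need N > k; got N={n}, k={params.k}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant series; MI estimated on tie-break noise only",
                      stacklevel=2)
    xj = _jitter(x, params.tie_noise_scale, params.seed)
    yj = _jitter(y, params.tie_noise_scale, params.seed)
    return _ksg_core(xj, yj, params.k, _psi_table(n))


def all_to_all_mi(
    window: np.ndarray,
    params: KSGParameters | None = None,
    labels: list[str] | None = None,
    tag: str | int = "window",
) -> MIMatrix:
    """Pairwise KSG mutual information between all channels of a window.

    ``window`` is samples x channels.  Each channel is jittered once and
    its sorted copy cached, so the n(n-1)/2 pair evaluations share the
    per-channel work; the result is exactly symmetric with a zero
    diagonal.
    """
    params = params or KSGParameters()
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] < 2:
        raise ValueError("window must be samples x channels with >= 2 channels")
    n, c = w.shape
    if n <= params.k:
        raise ValueError(f"need N > k; got N={n}, k={params.k}")
    psi_table = _psi_table(n)
    cols = [_jitter(w[:, i], params.tie_noise_scale, params.seed) for i in range(c)]
    sorted_cols = [np.sort(col) for col in cols]
    values = np.zeros((c, c))
    for i in range(c):
        for j in range(i + 1, c):
            try:
                mi = _ksg_core(cols[i], cols[j], params.k, psi_table,
                               sorted_cols[i], sorted_cols[j])
            except Exception as exc:  # re-raise with channel identities
                raise RuntimeError(f"MI estimation failed for pair ({i}, {j})") from exc
            values[i, j] = values[j, i] = mi
    return MIMatrix(values, labels or [], tag)


def average_mi(windows: list[MIMatrix]) -> MIMatrix:
    """Elementwise mean of per-window MI matrices, tagged ``averaged``."""
    if not windows:
        raise ValueError("need at least one MI matrix to average")
    shape = windows[0].values.shape
    if any(m.values.shape != shape for m in windows):
        raise ValueError("all MI matrices must share a shape")
    mean = np.mean([m.values for m in windows], axis=0)
    return MIMatrix(mean, list(windows[0].labels), "averaged")


def windowed_average_mi(
    window_set, params: KSGParameters | None = None, labels: list[str] | None = None
) -> tuple[MIMatrix, list[MIMatrix]]:
    """Per-window all-to-all MI plus the across-window average."""
    per_window = [
        all_to_all_mi(w, params, labels, tag=i)
        for i, w in enumerate(window_set.windows)
    ]
    return average_mi(per_window), per_window
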