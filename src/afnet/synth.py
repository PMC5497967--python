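"""Synthetic multi-electrode AF recordings with a planted coupling network.

No patient electrograms are available, so every downstream stage is
exercised on synthetic data that emulates the salient statistics of
basket-catheter recordings during atrial fibrillation:

* quasi-periodic atrial activations with per-train cycle lengths drawn
  from the AF range (120-240 ms), rendered as biphasic
  derivative-of-Gaussian deflections 10-20 ms wide;
* a planted pairwise coupling network: each ground-truth edge owns a
  shared latent activation-time train, and a node's event stream is the
  per-event mixture of its incident shared trains (a fraction ``c_e`` of
  each shared train's events, the same events for both endpoints) and
  its private train (the remaining ``1 - sum(c_e)`` fraction), so linked
  channels share a fraction ``c`` of their activation times exactly (up
  to independent jitter) while unlinked channels keep identical marginal
  statistics;
* additive far-field ventricular QRS-T deflections locked to a slower
  quasi-regular RR rhythm, with a synthetic surface-ECG reference
  channel, so template subtraction can be tested end to end.

The generator makes no attempt at biophysical tissue simulation; the
deflection morphology is electrogram-like but otherwise arbitrary, which
is irrelevant to an information-theoretic analysis.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .recording import MultiChannelRecording


# --------------------------------------------------------------------------
# electrode layout


@dataclass(frozen=True)
class ElectrodeLayout:
    """Basket-catheter layout: splines lettered a.., electrodes numbered 1..

    Labels are spline-major (a1..a8, b1..b8, ...), matching the
    conventional naming of a 64-pole basket (8 splines x 8 electrodes,
    9-11 mm inter-electrode spacing).
    """

    n_splines: int
    electrodes_per_spline: int
    labels: tuple[str, ...]
    inter_electrode_spacing_mm: float = 10.0

    @property
    def n_channels(self) -> int:
        return self.n_splines * self.electrodes_per_spline


def generate_basket_layout(n_splines: int = 8, per_spline: int = 8) -> ElectrodeLayout:
    """Enumerate basket electrode labels in spline-major order."""
    if n_splines < 1 or per_spline < 1:
        raise ValueError("spline and electrode counts must be >= 1")
    if n_splines > 26:
        raise ValueError("at most 26 splines (single-letter names)")
    labels = tuple(
        f"{string.ascii_lowercase[s]}{e + 1}"
        for s in range(n_splines)
        for e in range(per_spline)
    )
    return ElectrodeLayout(n_splines, per_spline, labels)


# --------------------------------------------------------------------------
# ground-truth coupling network


@dataclass
class GroundTruthNetwork:
    """Planted functional-coupling network for the simulator.

    ``coupling_strength[i, j]`` in [0, 1] is defined where
    ``adjacency[i, j] == 1`` and zero elsewhere.
    """

    adjacency: np.ndarray
    coupling_strength: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-edges are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        c = np.asarray(self.coupling_strength, dtype=float)
        if c.shape != a.shape:
            raise ValueError("coupling_strength shape must match adjacency")
        if np.any((c < 0) | (c > 1)):
            raise ValueError("coupling strengths must lie in [0, 1]")
        if np.any((a == 0) & (c != 0)):
            raise ValueError("coupling defined on a non-edge")
        self.adjacency = a.astype(int)
        self.coupling_strength = c

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))

    def with_coupling(self, coupling: float) -> "GroundTruthNetwork":
        """Same topology with a uniform coupling strength on every edge."""
        return GroundTruthNetwork(self.adjacency, self.adjacency * float(coupling))


def generate_planted_network(
    n_nodes: int,
    model: str,
    *,
    coupling: float = 0.5,
    k: int | None = None,
    p: float | None = None,
    m: int | None = None,
    n_bridges: int | None = None,
    triangle_coupling: float = 0.3,
    bridge_coupling: float = 0.4,
    bridge_layout: str = "random",
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Generate a ground-truth network from a named generative model.

    Parameters
    ----------
    model:
        ``"lattice"`` (ring lattice, each node linked to its ``k``
        nearest neighbours), ``"smallworld"`` (Watts-Strogatz with
        ``k`` neighbours and rewiring probability ``p``),
        ``"random"`` (uniform G(n, m) with ``m`` edges),
        ``"matching"`` (random perfect/maximal matching of disjoint
        edges, convenient for transitivity-free planted-edge tests), or
        ``"clustered"`` (disjoint triangles plus random bridges; see
        :func:`generate_clustered_network` — the per-edge couplings come
        from ``triangle_coupling``/``bridge_coupling``, not ``coupling``).
    coupling:
        Uniform coupling strength placed on every edge (ignored by the
        ``clustered`` model, which is deliberately non-uniform).
    """
    if model == "clustered":
        return generate_clustered_network(
            n_nodes, n_bridges=n_bridges, triangle_coupling=triangle_coupling,
            bridge_coupling=bridge_coupling, bridge_layout=bridge_layout,
            seed=seed,
        )
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if model == "lattice":
        k = 2 if k is None else k
        g = nx.watts_strogatz_graph(n_nodes, k, 0.0, seed=seed)
    elif model == "smallworld":
        k = 4 if k is None else k
        p = 0.1 if p is None else p
        if not 0.0 <= p <= 1.0:
            raise ValueError("rewiring probability must lie in [0, 1]")
        g = nx.watts_strogatz_graph(n_nodes, k, p, seed=seed)
    elif model == "random":
        if m is None:
            raise ValueError("random model requires m")
        if m > max_edges:
            raise ValueError(f"m = {m} exceeds max edge count {max_edges}")
        g = nx.gnm_random_graph(n_nodes, m, seed=seed)
    elif model == "matching":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_nodes)
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(
            (int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(n_nodes // 2)
        )
    elif model == "fragmented":
        # one long chain + disjoint dyads + leftover isolated nodes:
        # a spatially disintegrated substrate (params: k = chain length,
        # m = number of dyads)
        chain_nodes = 7 if k is None else int(k)
        n_dyads = 3 if m is None else int(m)
        if chain_nodes + 2 * n_dyads > n_nodes:
            raise ValueError("fragmented model: chain + dyads exceed n_nodes")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_nodes)
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        chain = perm[:chain_nodes]
        g.add_edges_from((int(a), int(b)) for a, b in zip(chain[:-1], chain[1:]))
        for d in range(n_dyads):
            i = perm[chain_nodes + 2 * d]
            j = perm[chain_nodes + 2 * d + 1]
            g.add_edge(int(i), int(j))
    elif model == "chains":
        # m = number of disjoint path components covering all nodes
        n_chains = 2 if m is None else int(m)
        if not 1 <= n_chains <= n_nodes // 2:
            raise ValueError("chains model needs 1 <= m <= n/2 components")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_nodes)
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        bounds = np.linspace(0, n_nodes, n_chains + 1).astype(int)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            block = perm[lo:hi]
            g.add_edges_from(
                (int(a), int(b)) for a, b in zip(block[:-1], block[1:])
            )
    else:
        raise ValueError(f"unknown model {model!r}")
    adj = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=int)
    return GroundTruthNetwork(adj, adj * float(coupling))


def generate_clustered_network(
    n_nodes: int,
    *,
    n_bridges: int | None = None,
    triangle_coupling: float = 0.3,
    bridge_coupling: float = 0.4,
    bridge_layout: str = "random",
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Disjoint triangles joined by strong inter-triangle bridges.

    The triangles supply local clustering; the bridges supply global
    shortcuts.  ``bridge_layout="random"`` places bridges between
    uniformly chosen triangle pairs (at most one per corner);
    ``"ring"`` chains the triangles into a deterministically connected
    necklace (triangle t to triangle t+1) and spends any remaining
    bridge budget on random chords between free corners — useful when
    the experiment needs the strong-edge skeleton alone to span the
    basket.  Couplings should respect the per-node sharing budget (a
    triangle corner with one bridge carries
    ``2 * triangle_coupling + bridge_coupling``); mild overshoot is
    tolerated and handled by event thinning in the simulator.  Node
    identities are permuted under ``seed``; leftover nodes (n mod 3)
    are attached by a single bridge each.
    """
    if n_nodes < 6:
        raise ValueError("need at least 6 nodes for two triangles")
    if 2 * triangle_coupling + bridge_coupling > 1.2:
        raise ValueError("corner coupling budget grossly exceeds 1")
    rng = np.random.default_rng(seed)
    n_tri = n_nodes // 3
    if n_bridges is None:
        n_bridges = n_tri
    perm = rng.permutation(n_nodes)
    tri = [perm[3 * t : 3 * t + 3] for t in range(n_tri)]
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    coup = np.zeros((n_nodes, n_nodes))

    def _add(i: int, j: int, c: float) -> bool:
        i, j = int(i), int(j)
        if i == j or adj[i, j]:
            return False
        adj[i, j] = adj[j, i] = 1
        coup[i, j] = coup[j, i] = c
        return True

    for t in range(n_tri):
        a, b, c = tri[t]
        for i, j in ((a, b), (b, c), (a, c)):
            _add(i, j, triangle_coupling)

    placed = 0
    if bridge_layout == "ring":
        for t in range(n_tri):
            if placed >= n_bridges:
                break
            placed += _add(tri[t][0], tri[(t + 1) % n_tri][1], bridge_coupling)
        # remaining budget: random chords between unused free corners
        free = [tri[t][2] for t in range(n_tri)]
        attempts = 0
        while placed < n_bridges and len(free) >= 2 and attempts < 100 * n_bridges:
            attempts += 1
            i1, i2 = rng.choice(len(free), size=2, replace=False)
            if _add(free[i1], free[i2], bridge_coupling):
                placed += 1
                for idx in sorted((int(i1), int(i2)), reverse=True):
                    free.pop(idx)
    elif bridge_layout == "random":
        free = {t: list(tri[t]) for t in range(n_tri)}
        attempts = 0
        while placed < n_bridges and attempts < 100 * n_bridges:
            attempts += 1
            t1, t2 = rng.choice(n_tri, size=2, replace=False)
            if not free[t1] or not free[t2]:
                continue
            i = free[t1].pop(int(rng.integers(len(free[t1]))))
            j = free[t2].pop(int(rng.integers(len(free[t2]))))
            if not _add(i, j, bridge_coupling):
                free[t1].append(i)
                free[t2].append(j)
    else:
        raise ValueError("bridge_layout must be 'random' or 'ring'")
    # attach any leftover nodes (n not divisible by 3) with one bridge
    for extra_idx in range(3 * n_tri, n_nodes):
        extra = int(perm[extra_idx])
        target = int(perm[int(rng.integers(3 * n_tri))])
        _add(extra, target, bridge_coupling)
    return GroundTruthNetwork(adj, coup)


# --------------------------------------------------------------------------
# simulation config


@dataclass
class SimulationConfig:
    """Knobs of the synthetic AF generator.

    Defaults mirror the acquisition conditions of basket-catheter AF
    mapping: 977 Hz sampling, 60-second recordings, atrial cycle
    lengths in 120-240 ms, ventricular RR around 750 ms.  ``noise_sd``
    is in units of the unit deflection amplitude (0.1 = SNR about 10,
    a free parameter of the generator).
    """

    fs_hz: float = 977.0
    duration_s: float = 60.0
    cycle_length_ms_range: tuple[float, float] = (120.0, 240.0)
    rr_interval_ms: float = 750.0
    rr_jitter_ms: float = 20.0
    timing_jitter_ms: float = 5.0
    pulse_width_ms_range: tuple[float, float] = (10.0, 20.0)
    noise_sd: float = 0.1
    ventricular_amplitude: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        lo, hi = self.cycle_length_ms_range
        if not 0 < lo <= hi:
            raise ValueError("invalid cycle length range")
        if self.duration_s * 1000.0 < hi:
            raise ValueError("duration too short for a single activation cycle")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.duration_s))


# --------------------------------------------------------------------------
# waveforms


def biphasic_pulse(width_ms: float, fs_hz: float) -> np.ndarray:
    """Biphasic derivative-of-Gaussian deflection, unit peak amplitude."""
    sigma_s = width_ms / 1000.0 / 4.0  # +-2 sigma covers the stated width
    half = int(np.ceil(3 * sigma_s * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    w = -t / sigma_s**2 * np.exp(-(t**2) / (2 * sigma_s**2))
    return w / np.abs(w).max()


def qrst_waveform(fs_hz: float, pre_r_ms: float = 50.0, post_r_ms: float = 400.0) -> np.ndarray:
    """Synthetic QRS-T complex: sharp biphasic QRS plus a slow T bump.

    Sample 0 of the returned vector is ``pre_r_ms`` before the R peak;
    the R peak (maximum) sits at index ``round(pre_r_ms * fs / 1000)``.
    """
    n_pre = int(round(pre_r_ms * fs_hz / 1000.0))
    n_post = int(round(post_r_ms * fs_hz / 1000.0))
    t = (np.arange(n_pre + n_post + 1) - n_pre) / fs_hz  # seconds relative to R
    qrs_sigma = 0.012
    qrs = np.exp(-(t**2) / (2 * qrs_sigma**2))
    q_dip = -0.25 * np.exp(-((t + 0.030) ** 2) / (2 * 0.008**2))
    s_dip = -0.30 * np.exp(-((t - 0.030) ** 2) / (2 * 0.008**2))
    t_wave = 0.30 * np.exp(-((t - 0.250) ** 2) / (2 * 0.050**2))
    return qrs + q_dip + s_dip + t_wave


def _event_train(
    rng: np.random.Generator, cfg: SimulationConfig, n_events: int
) -> np.ndarray:
    """Quasi-periodic activation-time train (ms): random base cycle + phase."""
    lo, hi = cfg.cycle_length_ms_range
    cycle = rng.uniform(lo, hi)
    phase = rng.uniform(0.0, cycle)
    return phase + cycle * np.arange(n_events)


def _render_events(
    trace: np.ndarray,
    times_ms: np.ndarray,
    amps: np.ndarray,
    pulse: np.ndarray,
    fs_hz: float,
) -> None:
    """Add an amplitude-scaled pulse at each event time (in place)."""
    half = (len(pulse) - 1) // 2
    n = len(trace)
    for t_ms, a in zip(times_ms, amps):
        center = int(round(t_ms / 1000.0 * fs_hz))
        lo, hi = center - half, center + half + 1
        if hi <= 0 or lo >= n:
            continue
        plo, phi = max(0, -lo), len(pulse) - max(0, hi - n)
        trace[max(0, lo) : min(n, hi)] += a * pulse[plo:phi]


def simulate_coupled_af(
    layout: ElectrodeLayout,
    truth: GroundTruthNetwork,
    cfg: SimulationConfig,
) -> MultiChannelRecording:
    """Simulate coupled quasi-periodic atrial electrograms.

    Each node owns a private activation-time train and each ground-truth
    edge owns a shared train.  A fraction ``c_e`` of each shared train's
    events is selected once per edge, and both endpoint nodes fire at
    exactly those selected times; the rest of a node's events come from
    its private train, thinned to keep the overall activation rate
    constant.  Linked channels therefore share a fraction ``c`` of their
    activation times (up to independent per-node timing jitter), which
    makes their mutual information rise monotonically with ``c``, while
    per-channel waveform, rate and amplitude statistics do not depend on
    the coupling.  Timing jitter and white amplitude noise are added per
    channel.
    """
    n = truth.n_nodes
    if n != layout.n_channels:
        raise ValueError(
            f"truth has {n} nodes but layout has {layout.n_channels} channels"
        )
    rng = np.random.default_rng(cfg.seed)
    duration_ms = cfg.duration_s * 1000.0
    lo_cycle = cfg.cycle_length_ms_range[0]
    n_events = int(duration_ms / lo_cycle) + 3

    private = [_event_train(rng, cfg, n_events) for _ in range(n)]
    edges = truth.edges
    # one thinning per edge, so both endpoints keep the SAME shared events
    shared_kept = {}
    for (i, j) in edges:
        train = _event_train(rng, cfg, n_events)
        mask = rng.random(n_events) < truth.coupling_strength[i, j]
        shared_kept[(i, j)] = train[mask]

    data = np.zeros((cfg.n_samples, n))
    for node in range(n):
        incident = [(e, truth.coupling_strength[e[0], e[1]])
                    for e in edges if node in e]
        total_c = sum(c for _, c in incident)
        parts = []
        scale = min(1.0, 1.0 / total_c) if total_c > 0 else 1.0
        for e, _ in incident:
            kept = shared_kept[e]
            if scale < 1.0:  # over-committed node: thin its share further
                kept = kept[rng.random(len(kept)) < scale]
            parts.append(kept)
        w_private = max(0.0, 1.0 - total_c)
        if w_private > 0:
            p = private[node]
            parts.append(p[rng.random(len(p)) < w_private])
        times = np.sort(np.concatenate(parts)) if parts else np.array([])
        times = times + rng.normal(0.0, cfg.timing_jitter_ms, size=times.shape)
        times = times[(times >= 0) & (times < duration_ms)]

        width = rng.uniform(*cfg.pulse_width_ms_range)
        pulse = biphasic_pulse(width, cfg.fs_hz)
        amps = rng.normal(1.0, 0.1, size=len(times)).clip(min=0.2)
        _render_events(data[:, node], times, amps, pulse, cfg.fs_hz)

    data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    return MultiChannelRecording(data, cfg.fs_hz, list(layout.labels))


# --------------------------------------------------------------------------
# ventricular far-field contamination


@dataclass
class ContaminatedRecording:
    """Recording with added ventricular far field, plus the ground truth."""

    recording: MultiChannelRecording
    ecg: np.ndarray
    r_peak_samples: np.ndarray
    template: np.ndarray
    channel_scales: np.ndarray

    def __iter__(self):
        # allow ``rec, ecg = add_ventricular_farfield(...)``
        return iter((self.recording, self.ecg))


def add_ventricular_farfield(
    rec: MultiChannelRecording, cfg: SimulationConfig
) -> ContaminatedRecording:
    """Superimpose QRS-T far-field deflections locked to an RR rhythm.

    The same QRS-T waveform, scaled per channel (log-normal spread around
    ``cfg.ventricular_amplitude``), is added at every R time on every
    channel.  The R times are embedded in a returned synthetic
    surface-ECG reference channel built from the same waveform at unit
    amplitude plus light measurement noise.
    """
    pre_r_ms, post_r_ms = 50.0, 400.0
    if cfg.rr_interval_ms <= pre_r_ms + post_r_ms:
        raise ValueError("rr_interval_ms must exceed the QRS-T template span")
    rng = np.random.default_rng(cfg.seed + 1)
    fs = rec.fs_hz
    n = rec.n_samples
    duration_ms = n / fs * 1000.0

    # beats are placed only where the full QRS-T span fits inside the
    # record, mirroring cropped clinical exports
    r_times = []
    t = rng.uniform(post_r_ms, cfg.rr_interval_ms)
    while t < duration_ms - post_r_ms:
        if t >= pre_r_ms:
            r_times.append(t)
        t += cfg.rr_interval_ms + rng.normal(0.0, cfg.rr_jitter_ms)
    r_times_ms = np.array(r_times)
    r_samples = np.round(r_times_ms / 1000.0 * fs).astype(int)

    template = qrst_waveform(fs, pre_r_ms, post_r_ms)
    n_pre = int(round(pre_r_ms * fs / 1000.0))

    scales = cfg.ventricular_amplitude * rng.lognormal(0.0, 0.3, size=rec.n_channels)
    if cfg.ventricular_amplitude == 0:
        scales = np.zeros(rec.n_channels)

    data = rec.data.copy()
    ecg = rng.normal(0.0, 0.02, size=n)
    for r in r_samples:
        lo = r - n_pre
        hi = lo + len(template)
        plo, phi = max(0, -lo), len(template) - max(0, hi - n)
        sl = slice(max(0, lo), min(n, hi))
        data[sl, :] += np.outer(template[plo:phi], scales)
        ecg[sl] += template[plo:phi]

    out = MultiChannelRecording(data, fs, list(rec.labels))
    return ContaminatedRecording(out, ecg, r_samples, template, scales)
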