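"""Synthetic generators for brain-like networks and block time series.

The study data (voxel-scale resting-state networks of five subjects) are not
redistributable, so every downstream stage is exercised on synthetic inputs
that reproduce the statistical structure the analysis assumes:

* voxel-scale binary networks that are small-world with an exponentially
  truncated power-law degree distribution,
* 90-node signed weighted ROI correlation matrices with positive and
  negative blocks,
* block-modular time series whose correlation matrix recovers the modular
  structure after thresholding.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from netres.networks import BinaryNetwork, CorrelationMatrix, TimeSeriesMatrix


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic dataset."""

    kind: str  # watts_strogatz | truncated_powerlaw | block_timeseries | signed_roi_blocks | brain_like
    n_nodes: int
    params: dict
    seed: int

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")


def gen_small_world(n: int, k: int, p: float, seed: int) -> BinaryNetwork:
    """Connected Watts-Strogatz ring lattice with rewiring probability p.

    Models the small-world architecture of functional brain networks: high
    clustering for local specialization plus low path length from shortcuts.
    """
    if k % 2 != 0:
        raise ValueError("k must be even")
    if not (n > k >= 2):
        raise ValueError("need n > k >= 2")
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    if p == 0:
        g = nx.watts_strogatz_graph(n, k, 0, seed=int(seed))
    else:
        g = nx.connected_watts_strogatz_graph(n, k, p, tries=200, seed=int(seed))
    net = BinaryNetwork(g, list(range(n)), {"kind": "watts_strogatz", "n": n, "k": k, "p": p, "seed": seed})
    return net


def truncated_powerlaw_pmf(exponent: float, cutoff: float, k_max: int, k_min: int = 1) -> np.ndarray:
    """p(k) ∝ k^(-exponent) * exp(-k/cutoff) on k_min..k_max (normalized)."""
    k = np.arange(k_min, k_max + 1, dtype=float)
    w = k ** (-exponent) * np.exp(-k / cutoff)
    return w / w.sum()


def gen_truncated_powerlaw(
    n: int,
    exponent: float,
    cutoff: float,
    seed: int,
    k_min: int = 1,
    max_resamples: int = 100,
) -> BinaryNetwork:
    """Configuration-model graph with exponentially truncated power-law degrees.

    Degrees are sampled from p(k) ∝ k^(-exponent)·exp(-k/cutoff); an odd
    degree sum is resampled (bounded retries).  Self-loops and multi-edges
    from stub pairing are removed afterwards (accepting a slight degree
    distortion, which is reported in ``meta['degree_distortion']``) rather
    than rejection-sampling whole graphs.
    """
    if exponent <= 1:
        raise ValueError("exponent must be > 1")
    if cutoff <= 1:
        raise ValueError("cutoff must be > 1")
    rng = np.random.default_rng(int(seed))
    k_max = n - 1
    pmf = truncated_powerlaw_pmf(exponent, cutoff, k_max, k_min)
    support = np.arange(k_min, k_max + 1)
    degrees = None
    for _ in range(max_resamples):
        cand = rng.choice(support, size=n, p=pmf)
        if cand.sum() % 2 == 0:
            degrees = cand
            break
    if degrees is None:
        raise RuntimeError("could not draw an even-sum degree sequence")
    multi = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31 - 1)))
    g = nx.Graph(multi)  # collapses multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    realized = np.array([g.degree(i) for i in range(n)])
    meta = {
        "kind": "truncated_powerlaw",
        "exponent": exponent,
        "cutoff": cutoff,
        "seed": seed,
        "target_degrees": degrees.tolist(),
        "degree_distortion": float(np.abs(realized - degrees).sum() / max(degrees.sum(), 1)),
    }
    return BinaryNetwork(g, list(range(n)), meta)


def gen_brain_like(
    n: int,
    exponent: float = 2.0,
    cutoff: float = 20.0,
    p_shortcut: float = 0.1,
    seed: int = 0,
    k_min: int = 2,
) -> BinaryNetwork:
    """Spatially embedded network with truncated power-law degrees.

    Emulates the two topological signatures reported for voxel-scale
    functional brain networks simultaneously: small-world clustering (links
    are laid down between spatially adjacent nodes on a ring, so neighbor
    sets overlap) and an exponentially truncated power-law degree
    distribution (per-node link quotas sampled from that law).  A fraction
    ``p_shortcut`` of link endpoints is rewired to uniformly random nodes,
    supplying the long-range shortcuts of small-world architecture.

    In contrast to its degree-preserving rewired twin, low-degree nodes here
    attach to their spatial neighbors rather than preferentially to hubs, so
    hub removal leaves the local lattice backbone intact.
    """
    rng = np.random.default_rng(int(seed))
    pmf = truncated_powerlaw_pmf(exponent, cutoff, k_max=max(n // 4, k_min + 1), k_min=k_min)
    support = np.arange(k_min, max(n // 4, k_min + 1) + 1)
    quota = rng.choice(support, size=n, p=pmf).astype(int)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    # connect outward by ring distance while both endpoints have quota left
    for d in range(1, n // 2 + 1):
        active = False
        for i in range(n):
            j = (i + d) % n
            if quota[i] > 0 and quota[j] > 0 and not g.has_edge(i, j) and i != j:
                g.add_edge(i, j)
                quota[i] -= 1
                quota[j] -= 1
                active = True
        if not active or quota.max() == 0:
            break
    # shortcut rewiring: move one endpoint of a random subset of edges
    edges = list(g.edges())
    for u, v in edges:
        if rng.random() < p_shortcut:
            w = int(rng.integers(n))
            if w not in (u, v) and not g.has_edge(u, w):
                g.remove_edge(u, v)
                g.add_edge(u, w)
    meta = {"kind": "brain_like", "exponent": exponent, "cutoff": cutoff, "p_shortcut": p_shortcut, "seed": seed}
    return BinaryNetwork(g, list(range(n)), meta)


def gen_block_timeseries(spec: GeneratorSpec) -> TimeSeriesMatrix:
    """Block-modular time series: shared block signal x loading + noise.

    Each node's series is ``sqrt(b)·global + sqrt(w-b)·block + sqrt(1-w)·ε``
    scaled by ``noise_sd``, so the expected pairwise correlation is ``w``
    within blocks and ``b`` between blocks.  No temporal autocorrelation is
    modeled; only the correlation structure matters downstream.

    params: n_blocks, within_corr (w), between_corr (b), n_timepoints,
    noise_sd (>0), optional loading_sd for node-level loading heterogeneity
    (creates hub nodes after thresholding).
    """
    p = spec.params
    n = spec.n_nodes
    n_blocks = int(p.get("n_blocks", 4))
    w = float(p.get("within_corr", 0.6))
    b = float(p.get("between_corr", 0.0))
    t = int(p.get("n_timepoints", 200))
    noise_sd = float(p.get("noise_sd", 1.0))
    loading_sd = float(p.get("loading_sd", 0.0))
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not (0 <= b < w <= 1):
        raise ValueError("need within_corr > between_corr >= 0")
    rng = np.random.default_rng(int(spec.seed))
    block_of = np.arange(n) * n_blocks // n  # remainder joins the last block
    global_sig = rng.standard_normal(t)
    block_sig = rng.standard_normal((n_blocks, t))
    eps = rng.standard_normal((n, t))
    loading = np.ones(n)
    if loading_sd > 0:
        loading = np.abs(1.0 + loading_sd * rng.standard_normal(n))
    shared = np.sqrt(b) * global_sig + np.sqrt(w - b) * block_sig[block_of]
    values = noise_sd * (loading[:, None] * shared + np.sqrt(1 - w) * eps)
    ts = TimeSeriesMatrix(values, [f"n{i}" for i in range(n)])
    return ts


def gen_signed_roi_corr(
    n: int = 90,
    n_blocks: int = 6,
    within_loading: float = 0.75,
    global_loading: float = 0.8,
    noise_var: float = 0.4,
    seed: int = 0,
) -> CorrelationMatrix:
    """Signed ROI-scale correlation matrix built from a latent factor model.

    Emulates a 90-region correlation matrix with positive and negative
    connection weights: blocks load on a shared global factor with
    alternating sign (anticorrelated systems, e.g. task-positive vs default
    mode) plus one private factor each.  Constructed as ``UUᵀ + D`` then
    normalized to unit diagonal, hence positive semidefinite by
    construction — eigenvalues are never patched.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(int(seed))
    block_of = np.arange(n) * n_blocks // n
    # factor 0: global with block-alternating sign; factors 1..n_blocks: private
    u = np.zeros((n, n_blocks + 1))
    sign = np.where(block_of % 2 == 0, 1.0, -1.0)
    lam = within_loading * (0.85 + 0.3 * rng.random(n))  # mild heterogeneity
    u[:, 0] = global_loading * sign * lam
    for bidx in range(n_blocks):
        mask = block_of == bidx
        u[mask, 1 + bidx] = lam[mask]
    c = u @ u.T
    cov = c + np.eye(n) * noise_var
    scale = 1.0 / np.sqrt(np.diag(cov))
    corr = cov * scale[:, None] * scale[None, :]
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, [f"roi{i}" for i in range(n)])
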