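"""Network construction from time series and correlation matrices.

Voxel-scale binary networks are obtained by thresholding positive Pearson
correlations, with the cutoff chosen so that the size-density relationship
log(N)/log(k) matches a target ratio ρ across datasets.  ROI-scale signed
weighted networks keep only strong links (by |r|) subject to the graph
remaining connected.  A degree-preserving rewired null network
(Maslov-Sneppen double-edge swaps) provides the topology null model.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from netres.networks import (
    BinaryNetwork,
    CorrelationMatrix,
    NodeId,
    SignedWeightedNetwork,
    TimeSeriesMatrix,
)


def pearson_corr(ts: TimeSeriesMatrix) -> CorrelationMatrix:
    """Pearson correlation of every node's series with every other.

    Raises if any series is constant (zero variance), naming the node.
    """
    sd = ts.values.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series for node {ts.node_ids[bad[0]]!r}")
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, list(ts.node_ids))


def _binary_from_threshold(corr: CorrelationMatrix, r_min: float, meta: dict) -> BinaryNetwork:
    a = np.triu(corr.values, k=1)
    ii, jj = np.nonzero(a > r_min)
    edges = [(corr.node_ids[i], corr.node_ids[j]) for i, j in zip(ii, jj)]
    return BinaryNetwork.from_edges(list(corr.node_ids), edges, meta)


def threshold_fixed(corr: CorrelationMatrix, r_min: float) -> BinaryNetwork:
    """Binary network with an edge wherever r > r_min (positive links only
    arise for r_min >= 0; nested thresholds give nested edge sets)."""
    if not (-1 < r_min < 1):
        raise ValueError("r_min must lie in (-1, 1)")
    return _binary_from_threshold(corr, r_min, {"r_threshold": r_min})


def threshold_by_size_density(corr: CorrelationMatrix, rho: float) -> BinaryNetwork:
    """Choose the correlation cutoff so that log(N)/log(k) ≈ ρ.

    The target mean degree is k = N^(1/ρ); only positive correlations are
    eligible as links.  The search is exact: off-diagonal positive r values
    are sorted and the cutoff placed so the achieved mean degree is closest
    to the target, ties broken deterministically toward the smallest cutoff.
    Achieved k, cutoff and density are recorded in ``meta``.
    """
    if rho <= 1:
        raise ValueError("rho must be > 1")
    n = corr.n_nodes
    k_target = n ** (1.0 / rho)
    if k_target < 1:
        raise ValueError(f"degenerate target mean degree {k_target:.3f} < 1")
    iu = np.triu_indices(n, k=1)
    vals = corr.values[iu]
    pos = np.sort(vals[vals > 0])[::-1]  # descending
    m_max = pos.size
    k_max = 2.0 * m_max / n
    if k_max < k_target - 1:
        raise ValueError(
            f"unattainable mean degree {k_target:.2f}: only {k_max:.2f} achievable "
            f"with positive correlations"
        )
    m_target = k_target * n / 2.0
    m_best = int(np.clip(round(m_target), 0, m_max))
    # candidate edge counts respecting ties in r (edge iff r > tau strictly)
    candidates = []
    for m in (m_best - 1, m_best, m_best + 1):
        if 0 <= m <= m_max:
            candidates.append(m)
    best = None
    for m in candidates:
        if m == 0:
            tau = float(pos[0])
        elif m == m_max:
            tau = float(np.nextafter(pos[-1], -np.inf))
        else:
            if pos[m - 1] == pos[m]:  # tie straddles the cut: unreachable m
                continue
            tau = float((pos[m - 1] + pos[m]) / 2.0)
        k_ach = 2.0 * m / n
        key = (abs(k_ach - k_target), tau)  # smallest tau among equal |k - target|
        if best is None or key < best[0]:
            best = (key, m, tau)
    _, m, tau = best
    net = _binary_from_threshold(
        corr,
        tau,
        {
            "rho": rho,
            "r_threshold": tau,
            "k_target": k_target,
            "k_achieved": 2.0 * m / n,
            "density": m / (n * (n - 1) / 2.0),
        },
    )
    return net


def roi_aggregate(ts: TimeSeriesMatrix, labels: Mapping[NodeId, NodeId]) -> TimeSeriesMatrix:
    """Average the series of all nodes sharing an ROI label (one mean series
    per distinct label, in first-appearance order)."""
    missing = [nid for nid in ts.node_ids if nid not in labels]
    if missing:
        raise ValueError(f"unlabeled node {missing[0]!r}")
    order: list[NodeId] = []
    members: dict[NodeId, list[int]] = {}
    for i, nid in enumerate(ts.node_ids):
        roi = labels[nid]
        if roi not in members:
            members[roi] = []
            order.append(roi)
        members[roi].append(i)
    out = np.vstack([ts.values[members[roi]].mean(axis=0) for roi in order])
    return TimeSeriesMatrix(out, order)


def signed_threshold_keep_connected(corr: CorrelationMatrix) -> SignedWeightedNetwork:
    """Keep only strong positive or negative links while preventing
    fragmentation.

    Finds the largest τ such that the graph with edges {|r| >= τ} is
    connected when sign is ignored, then returns the signed weighted edges
    at that τ.  τ equals the smallest |r| on the maximum-|r| spanning tree
    (the percolation threshold), found by adding edges in decreasing |r|
    under union-find until the graph connects.
    """
    n = corr.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = corr.values[iu, ju]
    mask = w != 0
    iu, ju, w = iu[mask], ju[mask], w[mask]
    order = np.argsort(-np.abs(w))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_comp = n
    tau = None
    for idx in order:
        a, b = find(int(iu[idx])), find(int(ju[idx]))
        if a != b:
            parent[a] = b
            n_comp -= 1
            if n_comp == 1:
                tau = float(abs(w[idx]))
                break
    if tau is None:
        raise ValueError("graph is disconnected even with every nonzero link kept")
    keep = np.abs(w) >= tau
    edges = [
        (corr.node_ids[int(i)], corr.node_ids[int(j)], float(v))
        for i, j, v in zip(iu[keep], ju[keep], w[keep])
    ]
    return SignedWeightedNetwork.from_weighted_edges(
        list(corr.node_ids), edges, {"tau": tau}
    )


def maslov_rewire(net: BinaryNetwork, n_swaps: int, seed: int) -> BinaryNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    Swaps that would create self-loops or multi-edges are rejected (and
    counted in ``meta['failed_swaps']``); the degree of every node and the
    edge count are unchanged.  n_swaps = 0 returns a copy.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    out = net.copy()
    if n_swaps == 0 or out.n_edges < 2:
        out.meta.update({"n_swaps": 0, "failed_swaps": 0})
        return out
    rng = np.random.default_rng(int(seed))
    g = out.graph
    edges = list(g.edges())
    failed = 0
    done = 0
    while done < n_swaps:
        e1, e2 = rng.integers(len(edges)), rng.integers(len(edges))
        if e1 == e2:
            failed += 1
            done += 1
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # propose u-x, v-y replacing u-v, x-y
        if len({u, v, x, y}) < 4 or g.has_edge(u, x) or g.has_edge(v, y):
            failed += 1
        else:
            g.remove_edge(u, v)
            g.remove_edge(x, y)
            g.add_edge(u, x)
            g.add_edge(v, y)
            edges[e1] = (u, x)
            edges[e2] = (v, y)
        done += 1
    out.meta.update({"n_swaps": n_swaps, "failed_swaps": failed})
    return out


def connected_component_sizes(adj: np.ndarray) -> np.ndarray:
    """Component sizes of a dense 0/1 adjacency (helper shared with metrics)."""
    if adj.shape[0] == 0:
        return np.array([], dtype=int)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return np.bincount(labels, minlength=n_comp)
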