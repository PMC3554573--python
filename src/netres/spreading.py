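"""Linear spreading-activation model and its Phase I/II machinery.

The model injects an external signal at 50 seed nodes at t=0 and iterates a
linear update for 100 steps: each node keeps a fraction (1-γ) of its own
activity (γ is the relaxation rate) and receives α times the normalized
weighted input pooled from its neighbors, where the connectivity matrix R
is the positive part of the correlation matrix with zero diagonal and each
column scaled to unit sum (a node's incoming weights sum to 1).

With the pooled flow term (the default), the asymptotic growth rate is
1 - γ + α·λmax but the finite-time total activity depends on how seed
activity projects onto the strength structure of the surviving network —
removing high-strength hubs concentrates weight on the seeds and raises the
final total, whereas a strictly conservative flow (``flow="conserved"``,
α·R·S with column-stochastic R) makes total activity provably invariant to
any node removal after renormalization and is kept only as a variant.

Phase I (total activity decays to zero) and Phase II (activity builds
exponentially in part of the system) are separated by the spectral radius
of the homogeneous update map crossing 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from netres._rng import substream
from netres.attack import AttackSpec, run_attack
from netres.networks import BinaryNetwork, CorrelationMatrix, NodeId


@dataclass
class SpreadMatrix:
    """Column-normalized nonnegative connectivity matrix.

    ``R[i, j]`` is the weight of the connection from node i to node j;
    column j holds node j's incoming weights, normalized to unit sum.
    Columns that have no positive input are left all-zero and listed in
    ``zero_columns`` (such nodes receive no flow; no teleportation is
    added).
    """

    R: np.ndarray
    node_ids: list[NodeId]
    zero_columns: list[NodeId] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if self.R.shape != (n, n):
            raise ValueError("R shape must match node_ids")
        if (self.R < 0).any():
            raise ValueError("R must be nonnegative")
        if np.abs(np.diag(self.R)).max(initial=0.0) > 0:
            raise ValueError("R diagonal must be 0")
        sums = self.R.sum(axis=0)
        nz = sums > 0
        if nz.any() and np.abs(sums[nz] - 1.0).max() > 1e-10:
            raise ValueError("every nonzero column of R must sum to 1")


@dataclass
class SAConfig:
    alpha: float = 1.0
    gamma: float = 0.96
    seeds: tuple[NodeId, ...] = ()
    n_steps: int = 100
    seed_amplitude: float = 1.0
    flow: str = "pooled"  # pooled | conserved

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0 <= self.gamma <= 1):
            warnings.warn(
                f"relaxation rate gamma={self.gamma} lies outside [0, 1]",
                stacklevel=2,
            )
        if self.flow not in ("pooled", "conserved"):
            raise ValueError("flow must be 'pooled' or 'conserved'")


@dataclass
class ActivityTrace:
    activity: np.ndarray  # N x (n_steps + 1)
    node_ids: list[NodeId]
    total_activity: np.ndarray  # length n_steps + 1
    phase: str | None = None  # "I" | "II"
    growing_nodes: set[NodeId] | None = None


def build_spread_matrix(
    corr: CorrelationMatrix, removed: set[NodeId] | None = None
) -> SpreadMatrix:
    """Construct R: drop removed nodes, zero negatives and the diagonal,
    scale each surviving column to unit sum (all-zero columns are left zero
    and reported)."""
    removed = removed or set()
    sub = corr.submatrix([n for n in corr.node_ids if n not in removed]) if removed else corr
    a = np.clip(sub.values, 0.0, None)
    np.fill_diagonal(a, 0.0)
    sums = a.sum(axis=0)
    nz = sums > 0
    r = np.zeros_like(a)
    r[:, nz] = a[:, nz] / sums[nz]
    zero_cols = [sub.node_ids[i] for i in np.flatnonzero(~nz)]
    return SpreadMatrix(r, list(sub.node_ids), zero_cols)


def homogeneous_map(R: SpreadMatrix, cfg: SAConfig) -> np.ndarray:
    """The matrix M with S_{t+1} = M S_t once the external input is gone."""
    n = len(R.node_ids)
    flow = R.R.T if cfg.flow == "pooled" else R.R
    return (1.0 - cfg.gamma) * np.eye(n) + cfg.alpha * flow


def simulate(R: SpreadMatrix, cfg: SAConfig) -> ActivityTrace:
    """Iterate the spreading-activation update for cfg.n_steps steps.

    The external signal is present only at t=0: the seed nodes start at
    ``seed_amplitude`` and everything else at 0, so the trace is linear in
    the seed amplitude.  Raises if a seed node is not present in R (seeds
    must be drawn from nodes that were not deleted).
    """
    if not cfg.seeds:
        raise ValueError("seeds must be nonempty")
    index = {nid: i for i, nid in enumerate(R.node_ids)}
    try:
        seed_idx = [index[s] for s in cfg.seeds]
    except KeyError as exc:
        raise ValueError(f"seed node {exc.args[0]!r} is not in the network") from None
    n = len(R.node_ids)
    m = homogeneous_map(R, cfg)
    s = np.zeros(n)
    s[seed_idx] = cfg.seed_amplitude
    trace = np.empty((n, cfg.n_steps + 1))
    trace[:, 0] = s
    for t in range(1, cfg.n_steps + 1):
        s = m @ s
        trace[:, t] = s
    return ActivityTrace(trace, list(R.node_ids), trace.sum(axis=0))


def classify_phase(
    trace: ActivityTrace, window: int = 20, growth_tol: float = 0.0, dead_band: float = 1e-8
) -> ActivityTrace:
    """Phase I vs Phase II from the log-slope of total activity.

    A least-squares slope of log(total activity) over the final ``window``
    steps above ``growth_tol`` (with a dead band against numerical noise)
    means exponential growth: Phase II.  ``growing_nodes`` are the nodes
    whose individual log-activity slope clears the same criterion.
    Identically-zero totals in the window are Phase I by definition.
    """
    total = trace.total_activity
    if window >= total.size:
        raise ValueError("window must be shorter than the trace")
    t = np.arange(window)
    tail = total[-window:]
    threshold = growth_tol + dead_band

    def log_slope(x: np.ndarray) -> float | None:
        if (x <= 0).any():
            return None
        return float(np.polyfit(t, np.log(x), 1)[0])

    slope = log_slope(tail)
    phase = "II" if (slope is not None and slope > threshold) else "I"
    growing: set[NodeId] = set()
    for i, nid in enumerate(trace.node_ids):
        s = log_slope(trace.activity[i, -window:])
        if s is not None and s > threshold:
            growing.add(nid)
    trace.phase = phase
    trace.growing_nodes = growing
    return trace


def tune_gamma(
    R: SpreadMatrix,
    alpha: float,
    seeds: tuple[NodeId, ...],
    n_steps: int = 100,
    flow: str = "pooled",
    tol: float = 1e-4,
    gamma_max: float | None = None,
) -> tuple[float, float]:
    """Largest relaxation rate γ that still yields Phase II, by bisection.

    Returns (γ, α/γ).  γ=0 must be Phase II and some γ <= gamma_max
    (default 1 + 2α) must be Phase I, otherwise an error is raised.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    gamma_max = gamma_max if gamma_max is not None else 1.0 + 2.0 * alpha

    def phase_at(g: float) -> str:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = SAConfig(alpha=alpha, gamma=g, seeds=tuple(seeds), n_steps=n_steps, flow=flow)
        return classify_phase(simulate(R, cfg)).phase

    lo = 0.0
    if phase_at(lo) != "II":
        raise ValueError("no gamma in the search range yields Phase II")
    hi = gamma_max
    if phase_at(hi) != "I":
        raise ValueError("search range upper bound is still Phase II; raise gamma_max")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if phase_at(mid) == "II":
            lo = mid
        else:
            hi = mid
    return lo, alpha / lo if lo > 0 else np.inf


def sa_attack_experiment(
    corr: CorrelationMatrix,
    ranking_net: BinaryNetwork,
    strategy: str,
    fractions: list[float],
    direction: str = "hub",
    n_seeds: int = 50,
    alpha: float = 1.0,
    gamma: float = 0.96,
    n_steps: int = 100,
    flow: str = "pooled",
    seed: int = 0,
    round_fraction: float = 0.05,
) -> "SAExperimentResult":
    """Final-total-activity curve across attack fractions.

    Node ranking runs on the thresholded binary network (recalculated every
    ``round_fraction`` round, the iterative protocol), while removal is
    applied to the unthresholded weighted connectivity: at each requested
    fraction R is rebuilt from the reduced correlation matrix and the model
    is re-simulated.  The seed nodes are drawn once from the nodes that
    survive every tested fraction and are held fixed, so the injected
    signal is identical across conditions.  The returned curve always
    includes fraction 0 (the intact network).
    """
    fractions = sorted(set(float(f) for f in fractions) - {0.0})
    if fractions and max(fractions) >= 1.0:
        raise ValueError("fractions must be < 1")
    n0 = ranking_net.n_nodes
    max_frac = max(fractions, default=0.0)
    n_rounds_total = int(np.ceil(max_frac / round_fraction)) if max_frac else 0
    spec = AttackSpec(
        strategy=strategy,
        direction=direction,
        fraction_per_round=round_fraction,
        n_rounds=n_rounds_total,
        recalculate=True,
        seed=seed,
    )
    schedule = run_attack(ranking_net, spec, compute_curves=False) if n_rounds_total else None
    removed_by_round: list[set[NodeId]] = schedule.removal_order if schedule else []
    ever_removed: set[NodeId] = set().union(*removed_by_round) if removed_by_round else set()
    pool = [n for n in corr.node_ids if n not in ever_removed]
    if len(pool) < n_seeds:
        raise ValueError("seed pool exhausted: not enough never-removed nodes")
    rng = substream(seed, "sa_seeds", strategy, direction)
    seeds = tuple(pool[i] for i in rng.choice(len(pool), size=n_seeds, replace=False))

    curve: list[tuple[float, float]] = []
    phases: list[str] = []
    removed: set[NodeId] = set()
    cum_rounds = 0
    for frac in [0.0] + fractions:
        target_rounds = int(np.ceil(frac / round_fraction)) if frac else 0
        while cum_rounds < target_rounds:
            removed |= removed_by_round[cum_rounds]
            cum_rounds += 1
        R = build_spread_matrix(corr, removed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = SAConfig(alpha=alpha, gamma=gamma, seeds=seeds, n_steps=n_steps, flow=flow)
        trace = classify_phase(simulate(R, cfg))
        curve.append((frac, float(trace.total_activity[-1])))
        phases.append(trace.phase)
    return SAExperimentResult(strategy, direction, seeds, curve, phases)


@dataclass
class SAExperimentResult:
    strategy: str
    direction: str
    seeds: tuple[NodeId, ...]
    curve: list[tuple[float, float]]  # (fraction_removed, final total activity)
    phases: list[str]

    def final_totals(self) -> dict[float, float]:
        return dict(self.curve)
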