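"""Targeted attack, antihub attack and random failure.

The iterative protocol removes a fixed 5% of the original node count per
round, ranked by the chosen centrality recomputed on the surviving graph
(recalculation is the default), and records the topology curve
(S/S0, E_glob, E_loc) after every round.  ROI-scale signed networks use a
single-shot 10% removal instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netres._rng import substream
from netres.metrics import (
    CentralityScores,
    TopologySummary,
    centrality,
    giant_component,
    topology_summary,
)
from netres.networks import BinaryNetwork, NodeId, SignedWeightedNetwork

STRATEGIES = ("degree", "leverage", "eigenvector", "betweenness", "random")


@dataclass
class AttackSpec:
    strategy: str = "degree"
    direction: str = "hub"  # hub | antihub; ignored for random
    fraction_per_round: float = 0.05
    n_rounds: int | None = None  # None = until the graph is empty
    recalculate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.direction not in ("hub", "antihub"):
            raise ValueError("direction must be 'hub' or 'antihub'")
        if not (0 < self.fraction_per_round <= 1):
            raise ValueError("fraction_per_round must be in (0, 1]")


@dataclass
class AttackResult:
    spec: AttackSpec
    removal_order: list[set[NodeId]]
    fraction_removed: list[float]  # cumulative, per curve point (round 0 = 0)
    curves: list[TopologySummary]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for rnd, (f, c) in enumerate(zip(self.fraction_removed, self.curves)):
            for metric, value in (
                ("S", c.S),
                ("S_over_S0", c.S_over_S0),
                ("E_glob", c.E_glob),
                ("E_loc", c.E_loc),
            ):
                rows.append(
                    {
                        "round": rnd,
                        "fraction_removed": f,
                        "metric": metric,
                        "value": value,
                        "strategy": self.spec.strategy,
                        "direction": self.spec.direction,
                    }
                )
        return pd.DataFrame(rows)


def select_targets(
    scores: CentralityScores,
    n_remove: int,
    direction: str = "hub",
    tiebreak_seed: int = 0,
) -> set[NodeId]:
    """The n_remove highest- (hub) or lowest- (antihub) scored nodes.

    Ties at the selection boundary are broken by a seeded uniform draw among
    the tied nodes (file order is an artifact; seeded randomness is
    reproducible and unbiased).
    """
    if n_remove == 0:
        return set()
    items = list(scores.scores.items())
    if n_remove > len(items):
        raise ValueError("n_remove exceeds surviving node count")
    sign = -1.0 if direction == "hub" else 1.0
    vals = np.array([sign * v for _, v in items])
    order = np.argsort(vals, kind="stable")
    cut = vals[order[n_remove - 1]]
    sure = [items[i][0] for i in order if vals[i] < cut][:n_remove]
    tied = [items[i][0] for i in order if vals[i] == cut]
    need = n_remove - len(sure)
    if need == len(tied):
        chosen = tied
    else:
        rng = substream(tiebreak_seed, "tiebreak")
        chosen = [tied[i] for i in rng.permutation(len(tied))[:need]]
    return set(sure) | set(chosen)


def _rank_scores(net, strategy: str, rng: np.random.Generator) -> CentralityScores:
    if strategy == "random":
        return CentralityScores(
            "random", "binary", {n: float(v) for n, v in zip(net.node_ids, rng.random(net.n_nodes))}
        )
    if strategy == "eigenvector" and net.n_edges == 0:
        # edgeless survivor graph: the metric is undefined, every node ties at 0
        return CentralityScores("eigenvector", "binary", {n: 0.0 for n in net.node_ids})
    return centrality(net, strategy)


def run_attack(net: BinaryNetwork, spec: AttackSpec, compute_curves: bool = True) -> AttackResult:
    """Iterative attack on a binary network.

    Per round: rank the surviving nodes (recomputing the centrality unless
    ``recalculate=False``, in which case the initial ranking is frozen),
    remove ceil(fraction_per_round * N_original) of them (fewer in the last
    round), and record the topology summary.  Curves include round 0 (the
    intact network); S is normalized to the intact giant component S0.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot attack an empty network")
    n0 = net.n_nodes
    s0 = giant_component(net)
    per_round = math.ceil(spec.fraction_per_round * n0)
    rng = substream(spec.seed, "attack", spec.strategy, spec.direction)
    current = net.copy()
    frozen = None if spec.recalculate else _rank_scores(current, spec.strategy, rng)
    def summarize(g: BinaryNetwork) -> TopologySummary:
        if compute_curves:
            return topology_summary(g, s0)
        s = giant_component(g)
        return TopologySummary(s, s / s0 if s0 else 0.0, np.nan, np.nan)

    removal_order: list[set[NodeId]] = []
    curves = [summarize(current)]
    fractions = [0.0]
    rnd = 0
    while current.n_nodes > 0:
        if spec.n_rounds is not None and rnd >= spec.n_rounds:
            break
        if spec.recalculate or frozen is None:
            scores = _rank_scores(current, spec.strategy, rng)
        else:
            scores = CentralityScores(
                frozen.metric,
                frozen.variant,
                {n: frozen.scores[n] for n in current.node_ids},
            )
        n_remove = min(per_round, current.n_nodes)
        targets = select_targets(
            scores, n_remove, spec.direction, tiebreak_seed=int(rng.integers(2**31 - 1))
        )
        current = current.remove_nodes(targets)
        removal_order.append(targets)
        curves.append(summarize(current))
        fractions.append((n0 - current.n_nodes) / n0)
        rnd += 1
    return AttackResult(spec, removal_order, fractions, curves)


def attack_weighted(
    net: SignedWeightedNetwork,
    strategy: str,
    direction: str = "hub",
    fraction: float = 0.10,
    seed: int = 0,
) -> tuple[set[NodeId], SignedWeightedNetwork]:
    """Single-shot removal of round(fraction*N) nodes from a signed network.

    Nodes are ranked by the weighted/signed centrality variants (strength,
    leverage/eigenvector on strengths, betweenness on |r|); random uses a
    seeded uniform ranking.  Returns the removed set and the induced
    surviving network.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = substream(seed, "attack_weighted", strategy, direction)
    scores = _rank_scores(net, strategy, rng)
    n_remove = round(fraction * net.n_nodes)
    targets = select_targets(scores, n_remove, direction, tiebreak_seed=int(rng.integers(2**31 - 1)))
    return targets, net.remove_nodes(targets)


def compare_curves(results: list[AttackResult]) -> pd.DataFrame:
    """Mean ± sd topology curves across replicate attack runs (long format).

    All results must share the same round structure (fractions).
    """
    if not results:
        raise ValueError("no results to compare")
    ref = results[0].fraction_removed
    for r in results[1:]:
        if len(r.fraction_removed) != len(ref) or not np.allclose(r.fraction_removed, ref):
            raise ValueError("attack results have mismatched round structure")
    frames = pd.concat([r.as_frame().assign(rep=i) for i, r in enumerate(results)])
    out = (
        frames.groupby(["strategy", "direction", "round", "fraction_removed", "metric"])["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=0))
        .reset_index()
    )
    return out
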