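"""Agent-based brain-inspired model (ABBM) on signed weighted networks.

Each node is a binary agent.  At every synchronous step an agent pools its
positively connected neighbors' states into a weighted on-fraction p, its
negatively connected neighbors' states into n (using |w|), thresholds both
(p >= tau_pos, n >= tau_neg), and looks up its next state in an elementary
(Wolfram) rule table addressed by the 3-bit code

    code = 4*own_state + 2*p_bit + n_bit      (most-to-least significant)

so ``rule_number`` bit ``code`` is the next state.  The convention is fixed
— rule numbers are meaningless without it — and isolated behind
:func:`step_states` so an alternative code construction can be swapped in.

The collective benchmark is the density-classification task: from a random
initial configuration, converge to all-on iff more than half the agents
started on.  The rule and thresholds that solve it are found with a genetic
algorithm on the intact network; attacked networks are evaluated with the
intact-trained rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from netres._rng import substream
from netres.attack import attack_weighted
from netres.networks import NodeId, SignedWeightedNetwork

GENOME_BITS = 24  # 8 rule bits + 8 tau_pos bits + 8 tau_neg bits


@dataclass(frozen=True)
class ABBMRule:
    rule_number: int
    tau_pos: float = 0.5
    tau_neg: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.rule_number <= 255):
            raise ValueError("rule_number must be in 0..255")
        if not (0 <= self.tau_pos <= 1 and 0 <= self.tau_neg <= 1):
            raise ValueError("thresholds must lie in [0, 1]")

    def table(self) -> np.ndarray:
        """8-entry output lookup indexed by the 3-bit neighborhood code."""
        return np.array([(self.rule_number >> b) & 1 for b in range(8)], dtype=np.uint8)


#: plain majority rule: next state = [p >= 1/2] regardless of own state or
#: negative input; output bit set exactly at codes with p_bit = 1.
MAJORITY_RULE = ABBMRule(0b11001100, tau_pos=0.5, tau_neg=0.5)


@dataclass
class AgentState:
    states: np.ndarray  # uint8 vector, one bit per node
    node_ids: list[NodeId]
    t: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.shape != (len(self.node_ids),):
            raise ValueError("states must hold one bit per node")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0/1")

    @property
    def density(self) -> float:
        return float(self.states.mean())


class _Coupling:
    """Cached positive/negative weight matrices for vectorized stepping."""

    def __init__(self, net: SignedWeightedNetwork):
        w = net.weight_matrix()
        self.wpos = np.clip(w, 0.0, None)
        self.wneg = np.abs(np.clip(w, None, 0.0))
        self.pos_strength = self.wpos.sum(axis=1)
        self.neg_strength = self.wneg.sum(axis=1)
        self.node_ids = list(net.node_ids)

    def step(self, s: np.ndarray, rule: ABBMRule) -> np.ndarray:
        """One synchronous update; ``s`` is (n,) or (n, trials) uint8."""
        squeeze = s.ndim == 1
        sm = s[:, None].astype(float) if squeeze else s.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.wpos @ sm
            np.divide(p, self.pos_strength[:, None], out=p, where=self.pos_strength[:, None] > 0)
            p[self.pos_strength == 0] = 0.0  # no positive links: p = 0
            q = self.wneg @ sm
            np.divide(q, self.neg_strength[:, None], out=q, where=self.neg_strength[:, None] > 0)
            q[self.neg_strength == 0] = 0.0
        code = 4 * s.reshape(sm.shape).astype(np.uint8) + 2 * (p >= rule.tau_pos) + (q >= rule.tau_neg)
        out = rule.table()[code]
        return out[:, 0] if squeeze else out


def abbm_step(states: AgentState, net: SignedWeightedNetwork, rule: ABBMRule) -> AgentState:
    """One synchronous ABBM update of every agent."""
    if list(states.node_ids) != list(net.node_ids):
        raise ValueError("states and network node order must match")
    nxt = _Coupling(net).step(states.states, rule)
    return AgentState(nxt, list(states.node_ids), states.t + 1)


def _run_batch(
    coupling: _Coupling, rule: ABBMRule, s0: np.ndarray, max_steps: int
) -> np.ndarray:
    """Final states after max_steps for a (n, trials) batch.

    Fixed points and period-2 cycles are detected and resolved analytically
    (the final state of a 2-cycle is fixed by step parity), so typical runs
    stop long before max_steps.
    """
    s_prev = None
    s = s0.astype(np.uint8).copy()
    final = s.copy()
    active = np.ones(s.shape[1], dtype=bool)
    for t in range(1, max_steps + 1):
        s_next = coupling.step(s[:, active], rule)
        cur = s[:, active]
        fixed = (s_next == cur).all(axis=0)
        if s_prev is not None:
            cyc = (s_next == s_prev[:, active]).all(axis=0) & ~fixed
        else:
            cyc = np.zeros_like(fixed)
        act_idx = np.flatnonzero(active)
        # fixed: final state is s_next forever
        final[:, act_idx[fixed]] = s_next[:, fixed]
        # 2-cycle: remaining steps decide which phase is seen at max_steps
        if cyc.any():
            rem = max_steps - t
            final[:, act_idx[cyc]] = s_next[:, cyc] if rem % 2 == 0 else cur[:, cyc]
        still = ~(fixed | cyc)
        s_prev = s.copy()
        s[:, act_idx] = s_next
        final[:, act_idx[still]] = s_next[:, still]
        active[act_idx[~still]] = False
        if not active.any():
            break
    return final


def classify_density(
    net: SignedWeightedNetwork,
    rule: ABBMRule,
    initial: AgentState,
    max_steps: int | None = None,
) -> bool:
    """Run the ABBM and score one density-classification trial.

    Success iff after max_steps (default 2N synchronous steps) the state is
    uniform and matches the majority of the initial configuration.  An
    exactly balanced initial state has no majority and is rejected.
    """
    n = net.n_nodes
    on = int(initial.states.sum())
    if 2 * on == n:
        raise ValueError("initial density exactly 0.5 has no majority")
    max_steps = 2 * n if max_steps is None else max_steps
    final = _run_batch(_Coupling(net), rule, initial.states[:, None], max_steps)[:, 0]
    if not (final == final[0]).all():
        return False
    return bool(final[0] == (1 if on > n - on else 0))


@dataclass
class DCPResult:
    density_grid: list[float]
    accuracy: list[float]
    trials_per_density: int

    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density": self.density_grid,
                "accuracy": self.accuracy,
                "trials": self.trials_per_density,
            }
        )


DEFAULT_DENSITY_GRID = tuple(
    round(x, 2) for x in np.arange(0.20, 0.81, 0.05) if abs(x - 0.5) > 1e-9
)


def _initial_batch(n: int, rho: float, trials: int, rng: np.random.Generator) -> np.ndarray:
    """(n, trials) initial states with round(rho*n) on-bits, uniformly placed."""
    on = int(round(rho * n))
    if 2 * on == n:
        raise ValueError(f"density {rho} puts exactly half the agents on")
    s = np.zeros((n, trials), dtype=np.uint8)
    for t in range(trials):
        s[rng.choice(n, size=on, replace=False), t] = 1
    return s


def accuracy_curve(
    net: SignedWeightedNetwork,
    rule: ABBMRule,
    density_grid=DEFAULT_DENSITY_GRID,
    trials_per_density: int = 50,
    max_steps: int | None = None,
    seed: int = 0,
) -> DCPResult:
    """Success fraction of the density-classification task per initial density."""
    n = net.n_nodes
    max_steps = 2 * n if max_steps is None else max_steps
    coupling = _Coupling(net)
    grid = sorted(float(r) for r in density_grid)
    rng = substream(seed, "dcp")
    acc = []
    for rho in grid:
        s0 = _initial_batch(n, rho, trials_per_density, rng)
        final = _run_batch(coupling, rule, s0, max_steps)
        on = s0.sum(axis=0)
        majority = (2 * on > n).astype(np.uint8)
        uniform = (final == final[0]).all(axis=0)
        acc.append(float((uniform & (final[0] == majority)).mean()))
    return DCPResult(grid, acc, trials_per_density)


@dataclass
class GAConfig:
    population_size: int = 50
    n_generations: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float = 1.0 / GENOME_BITS
    elitism_count: int = 2
    fitness_trials: int = 100
    tournament_size: int = 2
    max_steps: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


def _genome_to_rule(genome: np.ndarray) -> ABBMRule:
    bits = genome.astype(int)
    rule = int((bits[:8] << np.arange(8)).sum())
    tau_pos = int((bits[8:16] << np.arange(8)).sum()) / 256.0
    tau_neg = int((bits[16:24] << np.arange(8)).sum()) / 256.0
    return ABBMRule(rule, tau_pos, tau_neg)


def ga_search(
    net: SignedWeightedNetwork, ga: GAConfig
) -> tuple[ABBMRule, pd.DataFrame]:
    """Genetic-algorithm search for a rule solving density classification.

    Genome: 24 bits (rule number + both thresholds quantized to 1/256).
    Fitness: mean task success over a fixed set of ``fitness_trials``
    initial states with densities uniform in (0,1) excluding 1/2 (the set is
    frozen at the start so elite fitness is stable and the best-fitness
    sequence is non-decreasing).  Tournament selection, single-point
    crossover, per-bit mutation, elitism.

    Returns the best rule and a per-generation best/mean fitness history.
    """
    rng = substream(ga.seed, "ga")
    n = net.n_nodes
    coupling = _Coupling(net)
    max_steps = 2 * n if ga.max_steps is None else ga.max_steps
    # frozen evaluation set
    trials = []
    while len(trials) < ga.fitness_trials:
        rho = rng.random()
        on = int(round(rho * n))
        if 2 * on == n or on == 0 or on == n:
            continue
        col = np.zeros(n, dtype=np.uint8)
        col[rng.choice(n, size=on, replace=False)] = 1
        trials.append(col)
    s0 = np.stack(trials, axis=1)
    majority = (2 * s0.sum(axis=0) > n).astype(np.uint8)

    cache: dict[bytes, float] = {}

    def fitness(genome: np.ndarray) -> float:
        key = np.packbits(genome).tobytes()
        if key not in cache:
            rule = _genome_to_rule(genome)
            final = _run_batch(coupling, rule, s0, max_steps)
            uniform = (final == final[0]).all(axis=0)
            cache[key] = float((uniform & (final[0] == majority)).mean())
        return cache[key]

    pop = rng.integers(0, 2, size=(ga.population_size, GENOME_BITS)).astype(np.uint8)
    history = []
    best_genome = None
    best_fit = -1.0
    for gen in range(ga.n_generations):
        fits = np.array([fitness(g) for g in pop])
        order = np.argsort(-fits, kind="stable")
        if fits[order[0]] > best_fit:
            best_fit = float(fits[order[0]])
            best_genome = pop[order[0]].copy()
        history.append({"generation": gen, "best": best_fit, "mean": float(fits.mean())})
        elite = pop[order[: ga.elitism_count]].copy()
        children = [*elite]
        while len(children) < ga.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population_size, size=ga.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]].copy())
            a, b = parents
            if rng.random() < ga.crossover_prob:
                cut = int(rng.integers(1, GENOME_BITS))
                a = np.concatenate([a[:cut], b[cut:]])
            flip = rng.random(GENOME_BITS) < ga.mutation_prob
            a = a ^ flip.astype(np.uint8)
            children.append(a)
        pop = np.stack(children[: ga.population_size])
    return _genome_to_rule(best_genome), pd.DataFrame(history)


ATTACK_VARIANTS = tuple(
    [(m, d) for m in ("degree", "leverage", "eigenvector", "betweenness") for d in ("hub", "antihub")]
    + [("random", "hub")]
)


def abbm_attack_experiment(
    net: SignedWeightedNetwork,
    rule_from_intact: ABBMRule,
    density_grid=DEFAULT_DENSITY_GRID,
    trials_per_density: int = 50,
    fraction: float = 0.10,
    variants=ATTACK_VARIANTS,
    max_steps: int | None = None,
    seed: int = 0,
) -> dict[tuple[str, str], DCPResult]:
    """Density-classification accuracy with the intact-trained rule on each
    10%-attacked network (hub/antihub per centrality + random), plus the
    intact network under key ('intact', '-')."""
    out: dict[tuple[str, str], DCPResult] = {}
    out[("intact", "-")] = accuracy_curve(
        net, rule_from_intact, density_grid, trials_per_density, max_steps, seed=seed
    )
    for strategy, direction in variants:
        _, reduced = attack_weighted(net, strategy, direction, fraction, seed=seed)
        out[(strategy, direction)] = accuracy_curve(
            reduced, rule_from_intact, density_grid, trials_per_density, max_steps, seed=seed
        )
    return out


def attack_table(results: dict[tuple[str, str], DCPResult]) -> pd.DataFrame:
    """Long-format comparison table across attack variants."""
    frames = []
    for (strategy, direction), res in results.items():
        frames.append(res.as_frame().assign(strategy=strategy, direction=direction))
    return pd.concat(frames, ignore_index=True)
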