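"""Constrained multi-objective evolutionary search for active modules.

A modified NSGA-II over binary membership vectors:

* **Initialisation** seeds one individual per top-scoring node (as many
  seeds as the population size, or every node if the population is
  larger) and grows each seed by its positive-scoring neighbours.
* **Variation** is single-point crossover on the bit vectors plus a
  growth mutation that adds a neighbouring node which either has a
  positive activity score or belongs to at least one pathway.
* **Connectivity constraint**: a module must induce a connected subgraph
  (positive algebraic connectivity). Disconnected or empty offspring are
  infeasible; every feasible solution dominates every infeasible one.
* **Clearing** marks all but one copy of each duplicated solution
  infeasible, so the population does not silt up with replicas.
* **Sorting and replacement** use fast non-dominated sorting and crowding
  distance; parents and offspring compete in a merged population of twice
  the size (elitist replacement).

The result is the feasible first front: connected modules that are
mutually non-dominated in (activity, pathway coverage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .graph import ScoredNetwork, is_connected
from .objectives import GeneSetCollection, ObjectiveVector, PathwayIndex, evaluate

__all__ = [
    "Individual",
    "SearchConfig",
    "ParetoResult",
    "initialize",
    "binary_tournament",
    "single_point_crossover",
    "mutate",
    "clearing",
    "fast_nondominated_sort",
    "crowding_distance",
    "evolve",
    "knee_point",
    "extreme_points",
]


@dataclass(eq=False)  # identity semantics; membership vectors compare via key()
class Individual:
    """One candidate module inside the evolutionary population."""

    selection: np.ndarray  # boolean membership vector over the node order
    objectives: ObjectiveVector | None = None
    feasible: bool = False
    rank: int = -1
    crowding: float = 0.0

    def copy(self) -> "Individual":
        return Individual(
            selection=self.selection.copy(),
            objectives=self.objectives,
            feasible=self.feasible,
            rank=self.rank,
            crowding=self.crowding,
        )

    @property
    def size(self) -> int:
        return int(self.selection.sum())

    def key(self) -> bytes:
        return np.packbits(self.selection).tobytes()


@dataclass(frozen=True)
class SearchConfig:
    """Run parameters of the evolutionary search.

    ``fdr_alpha`` defaults to the conventional 0.05 FDR level; stringent
    levels (e.g. 1e-4) are appropriate when most genes are significant and
    module size must be reined in. ``tournament_skip_dup_fraction`` is the
    duplicate fraction beyond which tournament selection is skipped and
    the whole population reproduces, relieving selection pressure once the
    population has largely converged.
    """

    population_size: int = 50
    generations: int = 200
    r_ratio: float = 0.6
    fdr_alpha: float = 0.05
    rng_seed: int = 0
    tournament_skip_dup_fraction: float = 0.5
    crossover_rate: float = 0.9
    mutation_additions: int = 1

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("r_ratio", "fdr_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("tournament_skip_dup_fraction", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mutation_additions < 0:
            raise ValueError("mutation_additions must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParetoResult:
    """Final feasible first front with full provenance."""

    front: list[Individual]
    config: SearchConfig
    history: list[dict]
    node_order: list[str]

    def genes(self, i: int) -> list[str]:
        sel = self.front[i].selection
        return [self.node_order[j] for j in np.flatnonzero(sel)]


# ---------------------------------------------------------------------------
# population mechanics
# ---------------------------------------------------------------------------


def _evaluate_individual(
    ind: Individual, net: ScoredNetwork, index: PathwayIndex, r_ratio: float
) -> None:
    ind.objectives = evaluate(net, index, ind.selection, r_ratio)
    ind.feasible = ind.size > 0 and is_connected(net, ind.selection)


def initialize(
    net: ScoredNetwork, cfg: SearchConfig, index: PathwayIndex | None = None
) -> list[Individual]:
    """Seed the population with small high-activity cores.

    The ``population_size`` top-scoring nodes (ties broken by gene id, all
    nodes if the population exceeds the network) each found one module,
    grown immediately by the seed's positive-scoring neighbours, so every
    initial individual is connected by construction.
    """
    if net.scores is None:
        raise ValueError("network must be scored before initialisation")
    if not np.any(net.scores > 0):
        raise ValueError(
            "no node has a positive activity score; increase the FDR level "
            "alpha to obtain a larger significance threshold tau"
        )
    order = sorted(range(net.n_nodes), key=lambda i: (-net.scores[i], net.node_order[i]))
    seeds = order[: min(cfg.population_size, net.n_nodes)]
    population = []
    for s in seeds:
        sel = np.zeros(net.n_nodes, dtype=bool)
        sel[s] = True
        nbrs = net.neighbor_indices[s]
        sel[nbrs[net.scores[nbrs] > 0]] = True
        population.append(Individual(selection=sel))
    return population


def _dominates_unconstrained(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    fa, fb = a.minimized, b.minimized
    return fa[0] <= fb[0] and fa[1] <= fb[1] and (fa[0] < fb[0] or fa[1] < fb[1])


def constrained_dominates(p: Individual, q: Individual) -> bool:
    """Constrained-dominance: feasibility first, Pareto dominance second."""
    if p.feasible and not q.feasible:
        return True
    if not p.feasible and q.feasible:
        return False
    return _dominates_unconstrained(p.objectives, q.objectives)


def fast_nondominated_sort(population: Sequence[Individual]) -> list[list[Individual]]:
    """Partition into fronts F0, F1, ... under constrained dominance and
    assign ``rank`` in place."""
    n = len(population)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if constrained_dominates(population[i], population[j]):
                dominated_by[i].append(j)
                counts[j] += 1
            elif constrained_dominates(population[j], population[i]):
                dominated_by[j].append(i)
                counts[i] += 1
    for i in range(n):
        if counts[i] == 0:
            population[i].rank = 0
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    population[j].rank = k + 1
                    nxt.append(j)
        fronts.append(nxt)
        k += 1
    return [[population[i] for i in f] for f in fronts if f]


def crowding_distance(front: Sequence[Individual]) -> None:
    """Assign NSGA-II crowding distances in place.

    Boundary individuals of each objective get infinity; interior ones the
    sum over objectives of the normalised gap between their neighbours.
    Fronts of size <= 2 are all-infinite.
    """
    m = len(front)
    if m == 0:
        return
    if m <= 2:
        for ind in front:
            ind.crowding = math.inf
        return
    for ind in front:
        ind.crowding = 0.0
    for obj in range(2):
        order = sorted(range(m), key=lambda i: front[i].objectives.minimized[obj])
        vals = [front[i].objectives.minimized[obj] for i in order]
        front[order[0]].crowding = math.inf
        front[order[-1]].crowding = math.inf
        span = vals[-1] - vals[0]
        if span == 0:
            continue
        for pos in range(1, m - 1):
            i = order[pos]
            if front[i].crowding != math.inf:
                front[i].crowding += (vals[pos + 1] - vals[pos - 1]) / span


def _duplicate_fraction(population: Sequence[Individual]) -> float:
    keys = {ind.key() for ind in population}
    return 1.0 - len(keys) / len(population)


def _tournament_winner(
    a: Individual, b: Individual, rng: np.random.Generator
) -> Individual:
    if a.feasible != b.feasible:
        return a if a.feasible else b
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a if rng.random() < 0.5 else b


def binary_tournament(
    population: Sequence[Individual],
    rng: np.random.Generator,
    skip_dup_fraction: float = 0.5,
) -> list[Individual]:
    """Select a parent pool of the population's size by binary tournaments.

    When the fraction of duplicated selections exceeds
    ``skip_dup_fraction`` the step is skipped entirely and the whole
    population reproduces, lowering selection pressure on a converged
    population.
    """
    if _duplicate_fraction(population) > skip_dup_fraction:
        return [ind for ind in population]
    n = len(population)
    pool = []
    for _ in range(n):
        i, j = rng.integers(0, n, size=2)
        pool.append(_tournament_winner(population[i], population[j], rng))
    return pool


def single_point_crossover(
    p1: Individual, p2: Individual, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Swap prefixes of the two parent bit vectors at a uniform cut point.

    The cut is drawn from 1..|V|-1 so both sides are non-trivial.
    Offspring may be disconnected; feasibility is decided later by the
    connectivity constraint, never repaired here.
    """
    n = p1.selection.size
    cut = int(rng.integers(1, n))
    c1 = np.concatenate([p1.selection[:cut], p2.selection[cut:]])
    c2 = np.concatenate([p2.selection[:cut], p1.selection[cut:]])
    return Individual(selection=c1), Individual(selection=c2)


def mutate(
    ind: Individual,
    net: ScoredNetwork,
    index: PathwayIndex,
    rng: np.random.Generator,
    additions: int = 1,
) -> Individual:
    """Growth mutation: add neighbouring nodes of the module that have a
    positive activity score or belong to at least one pathway.

    Up to ``additions`` eligible neighbours are drawn uniformly without
    replacement; with no eligible neighbour the individual is returned
    unchanged. Only neighbours are added, so a connected module stays
    connected.
    """
    sel = ind.selection
    members = np.flatnonzero(sel)
    if members.size == 0 or additions == 0:
        return ind
    nbrs = np.unique(np.concatenate([net.neighbor_indices[i] for i in members]))
    nbrs = nbrs[~sel[nbrs]]
    eligible = nbrs[(net.scores[nbrs] > 0) | index.member_mask[nbrs]]
    if eligible.size == 0:
        return ind
    k = min(additions, eligible.size)
    chosen = rng.choice(eligible, size=k, replace=False)
    new_sel = sel.copy()
    new_sel[chosen] = True
    return Individual(selection=new_sel)


def clearing(population: Sequence[Individual]) -> None:
    """Mark all but the first copy of each duplicated selection infeasible.

    The surviving representative keeps the feasibility it earned from the
    connectivity constraint; the cleared replicas are dominated by every
    feasible solution and disappear at replacement.
    """
    seen: set[bytes] = set()
    for ind in population:
        k = ind.key()
        if k in seen:
            ind.feasible = False
        else:
            seen.add(k)


def _truncate(fronts: list[list[Individual]], n: int) -> list[Individual]:
    survivors: list[Individual] = []
    for front in fronts:
        crowding_distance(front)
        if len(survivors) + len(front) <= n:
            survivors.extend(front)
        else:
            room = n - len(survivors)
            # stable sort: ties keep their front order, deterministic
            ranked = sorted(front, key=lambda ind: -ind.crowding)
            survivors.extend(ranked[:room])
            break
    return survivors


def evolve(
    net: ScoredNetwork,
    col: GeneSetCollection | PathwayIndex,
    cfg: SearchConfig,
) -> ParetoResult:
    """Run the full generational loop and return the feasible first front.

    Fully reproducible from ``cfg.rng_seed``: all stochastic choices
    (tournaments, cut points, mutation draws) come from one seeded
    generator, and all tie-breaks are deterministic.
    """
    index = col if isinstance(col, PathwayIndex) else PathwayIndex(col, net)
    rng = np.random.default_rng(cfg.rng_seed)

    population = initialize(net, cfg, index)
    for ind in population:
        _evaluate_individual(ind, net, index, cfg.r_ratio)
    clearing(population)
    fronts = fast_nondominated_sort(population)
    for front in fronts:
        crowding_distance(front)

    history: list[dict] = []
    n = len(population)
    for gen in range(cfg.generations):
        pool = binary_tournament(population, rng, cfg.tournament_skip_dup_fraction)
        offspring: list[Individual] = []
        for i in range(0, n, 2):
            p1 = pool[i]
            p2 = pool[(i + 1) % n]
            if rng.random() < cfg.crossover_rate:
                c1, c2 = single_point_crossover(p1, p2, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            offspring.append(mutate(c1, net, index, rng, cfg.mutation_additions))
            if len(offspring) < n:
                offspring.append(mutate(c2, net, index, rng, cfg.mutation_additions))
        for ind in offspring:
            _evaluate_individual(ind, net, index, cfg.r_ratio)

        merged = list(population) + offspring
        clearing(merged)
        fronts = fast_nondominated_sort(merged)
        population = _truncate(fronts, n)

        feas = [ind for ind in population if ind.feasible]
        history.append(
            {
                "generation": gen,
                "best_s_a": max((i.objectives.s_a for i in feas), default=float("nan")),
                "best_r_a": max((i.objectives.r_a for i in feas), default=0),
                "n_feasible": len(feas),
            }
        )

    # final front: rank-0 feasible, deduplicated
    fast_nondominated_sort(population)
    seen: set[bytes] = set()
    front = []
    for ind in sorted(
        (i for i in population if i.rank == 0 and i.feasible),
        key=lambda i: (-i.objectives.s_a, i.objectives.r_a),
    ):
        if ind.key() not in seen:
            seen.add(ind.key())
            front.append(ind)
    return ParetoResult(
        front=front, config=cfg, history=history, node_order=list(net.node_order)
    )


# ---------------------------------------------------------------------------
# front analysis
# ---------------------------------------------------------------------------


def extreme_points(result: ParetoResult) -> tuple[int, int]:
    """Indices of the max-S_A and max-R_A front members (ties by the other
    objective, then smaller module)."""
    front = result.front
    if not front:
        raise ValueError("empty front")
    i_s = min(
        range(len(front)),
        key=lambda i: (-front[i].objectives.s_a, -front[i].objectives.r_a, front[i].size),
    )
    i_r = min(
        range(len(front)),
        key=lambda i: (-front[i].objectives.r_a, -front[i].objectives.s_a, front[i].size),
    )
    return i_s, i_r


def knee_point(result: ParetoResult) -> int:
    """Index of the knee: the front member with maximum perpendicular
    distance from the line joining the two extremes, computed on min-max
    normalised objectives. Degenerate fronts return the max-S_A extreme."""
    front = result.front
    if not front:
        raise ValueError("empty front")
    i_s, i_r = extreme_points(result)
    s = np.array([ind.objectives.s_a for ind in front], dtype=float)
    r = np.array([ind.objectives.r_a for ind in front], dtype=float)
    s_span = s.max() - s.min()
    r_span = r.max() - r.min()
    if len(front) < 3 or s_span == 0 or r_span == 0:
        return i_s
    sn = (s - s.min()) / s_span
    rn = (r - r.min()) / r_span
    p1 = np.array([sn[i_s], rn[i_s]])
    p2 = np.array([sn[i_r], rn[i_r]])
    d = p2 - p1
    norm = np.hypot(*d)
    if norm == 0:
        return i_s
    dist = np.abs(d[0] * (p1[1] - rn) - d[1] * (p1[0] - sn)) / norm
    return int(np.argmax(dist))
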