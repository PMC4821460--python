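"""Clonal-selection immune search over DAG space, guided by the K2 score.

A candidate network is an *antibody*: a DAG plus its cached log-K2 affinity.
Each generation rebuilds the population from an elitist memory set plus
freshly constructed greedy solutions, clones the top-affinity fraction,
perturbs the clones by neighbourhood crossover and add/delete/reverse
mutations, merges, removes duplicate-affinity antibodies (suppression), and
memorizes the best survivors.  The best antibody ever seen is the answer.

All randomness flows through one ``numpy.random.Generator`` seeded once per
run, consumed in a fixed documented order, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .discretize import DiscreteDataset
from .graph import Dag, incident_arcs, is_acyclic, try_add_arc, try_reverse_arc, delete_arc
from .scoring import K2Scorer

__all__ = [
    "Antibody",
    "ImmuneParams",
    "SearchResult",
    "construct_solution",
    "init_population",
    "clonal_select",
    "crossover_step",
    "mutate_step",
    "suppress",
    "immune_search",
    "ImmuneStructureLearner",
]


@dataclass
class Antibody:
    """A candidate network and its log-K2 affinity (None until scored)."""

    dag: Dag
    affinity: float | None = None

    def clone(self) -> "Antibody":
        # Dag is immutable, so sharing the graph object is a deep structural copy
        return Antibody(self.dag, self.affinity)


@dataclass(frozen=True)
class ImmuneParams:
    """Search hyperparameters; defaults follow the reference configuration
    N=80, T=150, M=70, P_s=0.5, P_c=0.6, P_m=0.4."""

    n_pop: int = 80
    t_max: int = 150
    m_mem: int = 70
    p_s: float = 0.5
    p_c: float = 0.6
    p_m: float = 0.4
    seed: int | None = None

    def __post_init__(self):
        if self.n_pop < 1:
            raise ValueError("n_pop must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not (0 <= self.m_mem < self.n_pop):
            raise ValueError("m_mem must satisfy 0 <= m_mem < n_pop")
        for name in ("p_s", "p_c", "p_m"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class SearchResult:
    """Outcome of one run: best antibody, best-so-far trace, and audit counters."""

    best: Antibody
    trace: np.ndarray
    crossovers_per_iter: list[int] = field(default_factory=list)
    mutations_per_iter: list[int] = field(default_factory=list)
    population_sizes: list[int] = field(default_factory=list)
    populations: list[list[Antibody]] | None = None


def _ensure_scored(ab: Antibody, scorer: K2Scorer) -> None:
    if ab.affinity is None:
        ab.affinity = scorer.log_score(ab.dag)


def construct_solution(scorer: K2Scorer, rng: np.random.Generator) -> Antibody:
    """Greedy randomized construction: first-improvement arc additions from empty.

    Each round scans the absent arcs in a fresh random order and adds the
    first one that keeps the graph acyclic and strictly raises the K2 score;
    construction stops when no addition improves.  The random scan order is
    what diversifies the constructed population; the result is a local
    maximum under arc addition only.
    """
    n = scorer.data.n_nodes
    dag = Dag(n)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    while True:
        candidates = [p for p in pairs if p not in dag.arcs]
        improved = False
        for k in rng.permutation(len(candidates)):
            i, j = candidates[k]
            if dag.reaches(j, i):  # addition would close a cycle
                continue
            if scorer.add_arc_gain(dag, i, j) > 0:
                dag = try_add_arc(dag, i, j)
                improved = True
                break
        if not improved:
            break
    return Antibody(dag, scorer.log_score(dag))


def init_population(
    memory: list[Antibody],
    scorer: K2Scorer,
    params: ImmuneParams,
    rng: np.random.Generator,
) -> list[Antibody]:
    """Memory antibodies plus freshly constructed ones, ``n_pop`` in total."""
    if len(memory) > params.m_mem:
        raise ValueError("memory exceeds its capacity")
    pop = [ab.clone() for ab in memory]
    while len(pop) < params.n_pop:
        pop.append(construct_solution(scorer, rng))
    return pop


def clonal_select(
    population: list[Antibody], p_s: float
) -> tuple[list[Antibody], list[Antibody]]:
    """Top ``floor(len(population) * p_s)`` antibodies (GS) and their clones (GSC).

    Sorting is stable on descending affinity, so equal-affinity ties keep
    population order and selection is deterministic.
    """
    if not population:
        raise ValueError("population is empty")
    n_sel = int(len(population) * p_s)
    order = sorted(range(len(population)), key=lambda k: -population[k].affinity)
    gs = [population[k] for k in order[:n_sel]]
    gsc = [ab.clone() for ab in gs]
    return gs, gsc


def crossover_step(gsc: list[Antibody], rng: np.random.Generator) -> bool:
    """One crossover attempt: swap the incident-arc sets of a shared node.

    Two distinct antibodies G_a, G_b and a node X_i are drawn uniformly; with
    A(i) the arcs touching X_i, the offspring are
    ``G_a' = G_a \\ A_a(i) | A_b(i)`` and symmetrically for G_b'.  The parents
    are replaced only when the neighbourhoods differ and both offspring are
    acyclic; a failed attempt leaves ``gsc`` unchanged but still consumes the
    attempt.  Returns True iff offspring were installed.
    """
    if len(gsc) < 2:
        raise ValueError("crossover needs at least two antibodies")
    a, b = rng.choice(len(gsc), size=2, replace=False)
    node = int(rng.integers(gsc[a].dag.n_nodes))
    ga, gb = gsc[a].dag, gsc[b].dag
    arcs_a, arcs_b = incident_arcs(ga, node), incident_arcs(gb, node)
    if arcs_a == arcs_b:
        return False
    new_a = (ga.arcs - arcs_a) | arcs_b
    new_b = (gb.arcs - arcs_b) | arcs_a
    if not (is_acyclic(ga.n_nodes, new_a) and is_acyclic(gb.n_nodes, new_b)):
        return False
    gsc[int(a)] = Antibody(Dag._unsafe(ga.n_nodes, frozenset(new_a)))
    gsc[int(b)] = Antibody(Dag._unsafe(gb.n_nodes, frozenset(new_b)))
    return True


def mutate_step(gsc: list[Antibody], rng: np.random.Generator) -> bool:
    """One mutation attempt: add, delete, or reverse an arc of one antibody.

    The antibody and one of the three strategies are drawn uniformly.
    Addition draws a child X_j, then a non-parent X_i, and adds X_i -> X_j
    unless that closes a cycle; deletion / reversion draw a present arc
    uniformly (sorted arc order, for seed stability).  Infeasible draws leave
    the antibody unchanged but consume the attempt.  Returns True on change.
    """
    if not gsc:
        raise ValueError("mutation needs at least one antibody")
    k = int(rng.integers(len(gsc)))
    dag = gsc[k].dag
    strategy = int(rng.integers(3))
    new_dag = None
    if strategy == 0:  # addition
        j = int(rng.integers(dag.n_nodes))
        pool = [i for i in range(dag.n_nodes) if i != j and i not in dag.parents_of(j)]
        if pool:
            i = pool[int(rng.integers(len(pool)))]
            new_dag = try_add_arc(dag, i, j)
    else:
        arcs = sorted(dag.arcs)
        if arcs:
            i, j = arcs[int(rng.integers(len(arcs)))]
            if strategy == 1:  # deletion
                new_dag = delete_arc(dag, i, j)
            else:  # reversion
                new_dag = try_reverse_arc(dag, i, j)
    if new_dag is None:
        return False
    gsc[k] = Antibody(new_dag)
    return True


def suppress(population: list[Antibody]) -> list[Antibody]:
    """Keep the first antibody of each distinct affinity value, drop the rest.

    Duplicate detection is by exact equality of the (float) affinity, the
    suppression rule as literally specified; structurally distinct antibodies
    that score identically are therefore conflated on purpose.
    """
    seen: set[float] = set()
    out = []
    for ab in population:
        if ab.affinity is None:
            raise ValueError("suppress requires scored antibodies")
        if ab.affinity not in seen:
            seen.add(ab.affinity)
            out.append(ab)
    return out


def immune_search(
    data: DiscreteDataset,
    params: ImmuneParams | None = None,
    *,
    record_populations: bool = False,
) -> SearchResult:
    """Run the full immune search and return the highest-affinity antibody.

    Per iteration t = 0..t_max-1: rebuild the population from memory plus new
    greedy constructions, score everything, clonally select and clone the top
    fraction, run ``floor(|GSC| * p_c)`` crossover attempts then
    ``floor(|GSC| * p_m)`` mutation attempts on the clones, merge GS with GSC,
    rescore, suppress duplicate affinities, and memorize the best
    ``min(m_mem, survivors)`` antibodies.  ``trace[t]`` is the best affinity
    seen up to iteration t (non-decreasing by construction).
    """
    params = params or ImmuneParams()
    scorer = K2Scorer(data)
    rng = np.random.default_rng(params.seed)
    memory: list[Antibody] = []
    best: Antibody | None = None
    trace: list[float] = []
    result = SearchResult(best=None, trace=None)  # type: ignore[arg-type]
    if record_populations:
        result.populations = []

    for _t in range(params.t_max):
        population = init_population(memory, scorer, params, rng)
        for ab in population:
            _ensure_scored(ab, scorer)
        gs, gsc = clonal_select(population, params.p_s)
        n_cross = int(len(gsc) * params.p_c)
        n_mut = int(len(gsc) * params.p_m)
        for _ in range(n_cross):
            crossover_step(gsc, rng)
        for _ in range(n_mut):
            mutate_step(gsc, rng)
        population = gs + gsc
        for ab in population:
            _ensure_scored(ab, scorer)
        population = suppress(population)
        by_affinity = sorted(range(len(population)), key=lambda k: -population[k].affinity)
        memory = [population[k].clone() for k in by_affinity[: params.m_mem]]
        iter_best = population[by_affinity[0]]
        if best is None or iter_best.affinity > best.affinity:
            best = iter_best.clone()
        trace.append(best.affinity)
        result.crossovers_per_iter.append(n_cross)
        result.mutations_per_iter.append(n_mut)
        result.population_sizes.append(len(population))
        if record_populations:
            result.populations.append([ab.clone() for ab in population])

    result.best = best
    result.trace = np.asarray(trace)
    return result


class ImmuneStructureLearner(BaseEstimator):
    """K2-scored effective-connectivity structure learner (immune search).

    Learns a directed acyclic network over the columns of a discretized
    observation matrix by maximizing the log-K2 score with a clonal-selection
    immune algorithm: elitist memory, greedy randomized construction,
    neighbourhood crossover, add/delete/reverse mutation, and
    duplicate-affinity suppression.

    Parameters
    ----------
    n_pop : int, default=80
        Population size N.
    n_iter : int, default=150
        Number of generations T.
    memory_size : int, default=70
        Elitist memory capacity M (best antibodies carried between
        generations; typical settings are 0.7-0.9 of ``n_pop``).
    p_select : float, default=0.5
        Clonal-selection fraction P_s: the top ``floor(N * p_select)``
        antibodies are cloned for variation each generation.
    p_crossover : float, default=0.6
        Crossover rate P_c: ``floor(|GSC| * p_crossover)`` attempts per
        generation.
    p_mutation : float, default=0.4
        Mutation rate P_m: ``floor(|GSC| * p_mutation)`` attempts per
        generation.
    random_state : int or None, default=None
        Seed for the single RNG stream driving the whole run.

    Attributes
    ----------
    dag_ : Dag
        Highest-scoring network found.
    arcs_ : frozenset of (int, int)
        Its arc set, ``(i, j)`` meaning column i -> column j.
    score_ : float
        Its natural-log K2 affinity.
    trace_ : ndarray of shape (n_iter,)
        Best score seen after each generation (non-decreasing).
    n_features_in_ : int
        Number of nodes (columns).

    Examples
    --------
    >>> from immunedag import benchmark
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> truth = benchmark.random_dag(4, 3, rng)
    >>> model = benchmark.sample_model(truth, arity=3, concentration=0.2, rng=rng)
    >>> data = benchmark.sample_observations(model, 500, rng)
    >>> est = ImmuneStructureLearner(n_pop=20, n_iter=15, memory_size=15,
    ...                              random_state=0).fit(data)
    >>> est.dag_.n_nodes
    4
    """

    def __init__(
        self,
        n_pop: int = 80,
        n_iter: int = 150,
        memory_size: int = 70,
        p_select: float = 0.5,
        p_crossover: float = 0.6,
        p_mutation: float = 0.4,
        random_state: int | None = None,
    ):
        self.n_pop = n_pop
        self.n_iter = n_iter
        self.memory_size = memory_size
        self.p_select = p_select
        self.p_crossover = p_crossover
        self.p_mutation = p_mutation
        self.random_state = random_state

    def _as_dataset(self, X) -> DiscreteDataset:
        if isinstance(X, DiscreteDataset):
            return X
        obs = np.asarray(X)
        if obs.ndim != 2 or obs.size == 0:
            raise ValueError("X must be a non-empty 2-D integer matrix")
        if obs.min() < 1:
            raise ValueError(
                "X must hold 1-based discrete codes; run EqualFrequencyDiscretizer first"
            )
        arity = obs.max(axis=0).astype(np.int64)
        return DiscreteDataset(obs, arity)

    def fit(self, X, y=None):
        """Learn the network from a (n_cases, n_nodes) matrix of 1-based codes
        or a :class:`DiscreteDataset`."""
        data = self._as_dataset(X)
        params = ImmuneParams(
            n_pop=self.n_pop,
            t_max=self.n_iter,
            m_mem=self.memory_size,
            p_s=self.p_select,
            p_c=self.p_crossover,
            p_m=self.p_mutation,
            seed=self.random_state,
        )
        result = immune_search(data, params)
        self.n_features_in_ = data.n_nodes
        self.dag_ = result.best.dag
        self.arcs_ = result.best.dag.arcs
        self.score_ = result.best.affinity
        self.trace_ = result.trace
        return self
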