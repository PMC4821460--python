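"""Synthetic ground-truth networks and datasets with known structure.

Two generators cover the two halves of the pipeline.  The discrete
Bayesian-network generator (random sparse DAG, Dirichlet conditional
probability tables, ancestral sampling) matches the K2 score's own model
class exactly and is the primary test vehicle.  The continuous generator
emulates the statistical shape of multi-subject simulated fMRI benchmarks —
a known sparse network, ~50 subjects of ~200 time points, linear parent
influence plus Gaussian noise — to exercise the per-subject discretization
path end to end; it makes no attempt at BOLD haemodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discretize import DiscreteDataset
from .graph import Dag

__all__ = [
    "GroundTruthModel",
    "ContinuousGenConfig",
    "random_dag",
    "sample_model",
    "sample_strong_model",
    "is_strong_model",
    "sample_observations",
    "generate_subjects",
]


@dataclass(frozen=True)
class GroundTruthModel:
    """A DAG plus per-node conditional probability tables.

    ``cpts[i]`` has shape (q_i, arity_i): one row per configuration of node
    i's parents (mixed-radix order, sorted parents, first most significant),
    each row a distribution over the node's values.
    """

    dag: Dag
    arities: np.ndarray
    cpts: tuple[np.ndarray, ...]
    seed: int | None = None

    def __post_init__(self):
        for i, table in enumerate(self.cpts):
            q = 1
            for p in self.dag.parents_of(i):
                q *= int(self.arities[p])
            if table.shape != (q, int(self.arities[i])):
                raise ValueError(f"CPT for node {i} has shape {table.shape}, expected {(q, int(self.arities[i]))}")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for node {i} must sum to 1")


@dataclass(frozen=True)
class ContinuousGenConfig:
    """Shape of the multi-subject continuous benchmark.

    Defaults mirror the common simulated-fMRI setting: 50 subjects of 200
    time points (a 10-min session at TR = 3 s), moderate causal weights and
    low additive noise.
    """

    n_subjects: int = 50
    n_timepoints: int = 200
    connection_strength: float = 0.4
    noise_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _topological_order(dag: Dag) -> list[int]:
    indeg = {v: len(dag.parents_of(v)) for v in range(dag.n_nodes)}
    queue = sorted(v for v, d in indeg.items() if d == 0)
    order = []
    while queue:
        v = queue.pop(0)
        order.append(v)
        for w in dag.children_of(v):
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
        queue.sort()
    return order


def random_dag(n_nodes: int, n_arcs: int, rng: np.random.Generator) -> Dag:
    """Uniform-topological-order sparse DAG with exactly ``n_arcs`` arcs."""
    max_arcs = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_arcs <= max_arcs):
        raise ValueError(f"n_arcs must lie in [0, {max_arcs}] for {n_nodes} nodes")
    order = rng.permutation(n_nodes)
    pairs = [
        (int(order[a]), int(order[b]))
        for a in range(n_nodes)
        for b in range(a + 1, n_nodes)
    ]
    chosen = rng.choice(len(pairs), size=n_arcs, replace=False)
    return Dag(n_nodes, [pairs[k] for k in sorted(int(c) for c in chosen)])


def sample_model(
    dag: Dag, arity: int, concentration: float, rng: np.random.Generator
) -> GroundTruthModel:
    """Draw each CPT row from a symmetric Dirichlet(``concentration``).

    Low concentration (e.g. 0.2) gives peaked rows, i.e. strong and
    identifiable parent-child dependencies; high concentration approaches
    uniform rows (no signal).
    """
    if arity < 2:
        raise ValueError("arity must be >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    arities = np.full(dag.n_nodes, int(arity), dtype=np.int64)
    cpts = []
    for i in range(dag.n_nodes):
        q = 1
        for p in dag.parents_of(i):
            q *= arity
        cpts.append(rng.dirichlet(np.full(arity, concentration), size=q))
    return GroundTruthModel(dag=dag, arities=arities, cpts=tuple(cpts))


def _exact_marginals(model: GroundTruthModel) -> np.ndarray:
    """Exact per-node marginals by enumerating the joint (small networks only)."""
    n = model.dag.n_nodes
    arities = [int(a) for a in model.arities]
    n_states = int(np.prod(arities))
    if n_states > 200_000:
        raise ValueError("network too large for exact marginal enumeration")
    order = _topological_order(model.dag)
    states = np.stack(
        np.meshgrid(*[np.arange(r) for r in arities], indexing="ij"), axis=-1
    ).reshape(n_states, n)
    prob = np.ones(n_states)
    for i in order:
        parents = model.dag.parents_of(i)
        config = np.zeros(n_states, dtype=np.int64)
        for p in parents:
            config = config * arities[p] + states[:, p]
        prob *= model.cpts[i][config, states[:, i]]
    marg = np.zeros((n, max(arities)))
    for i in range(n):
        for k in range(arities[i]):
            marg[i, k] = prob[states[:, i] == k].sum()
    return marg


def is_strong_model(
    model: GroundTruthModel, min_marginal: float = 0.05, min_effect: float = 0.2
) -> bool:
    """True when every dependency in the model is strong enough to detect.

    Two requirements: (a) every node visits each of its values with marginal
    probability at least ``min_marginal`` (a nearly constant node renders its
    outgoing arcs invisible); (b) for every arc, changing the parent's value
    while holding co-parents fixed shifts the child's conditional distribution
    by at least ``min_effect`` in total variation for some setting.
    """
    marg = _exact_marginals(model)
    for i in range(model.dag.n_nodes):
        if marg[i, : int(model.arities[i])].min() < min_marginal:
            return False
    for i in range(model.dag.n_nodes):
        parents = model.dag.parents_of(i)
        if not parents:
            continue
        table = model.cpts[i]
        radices = [int(model.arities[p]) for p in parents]
        shaped = table.reshape(*radices, int(model.arities[i]))
        for axis, _p in enumerate(parents):
            rolled = np.moveaxis(shaped, axis, 0)
            flat = rolled.reshape(rolled.shape[0], -1, rolled.shape[-1])
            tv = 0.0
            for a in range(flat.shape[0]):
                for b in range(a + 1, flat.shape[0]):
                    tv = max(tv, 0.5 * np.abs(flat[a] - flat[b]).sum(axis=1).max())
            if tv < min_effect:
                return False
    return True


def sample_strong_model(
    dag: Dag,
    arity: int,
    concentration: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> GroundTruthModel:
    """Draw Dirichlet CPTs, rejecting models that fail :func:`is_strong_model`.

    Low-concentration Dirichlet rows are usually peaked (strong conditional
    dependence) but occasionally degenerate — e.g. a root whose marginal puts
    ~99% mass on one value, which makes its outgoing arcs undetectable at any
    sample size.  Rejection sampling keeps the Dirichlet shape while
    guaranteeing that every arc carries a detectable signal, which is what a
    recovery benchmark needs from its ground truth.
    """
    for _ in range(max_tries):
        model = sample_model(dag, arity, concentration, rng)
        if is_strong_model(model):
            return model
    raise RuntimeError(f"no strong model found in {max_tries} draws")


def sample_observations(
    model: GroundTruthModel, n_cases: int, rng: np.random.Generator
) -> DiscreteDataset:
    """Ancestral sampling of ``n_cases`` rows; output plugs into the K2 scorer."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    n = model.dag.n_nodes
    obs = np.zeros((n_cases, n), dtype=np.int64)
    for i in _topological_order(model.dag):
        parents = model.dag.parents_of(i)
        table = model.cpts[i]
        if not parents:
            config = np.zeros(n_cases, dtype=np.int64)
        else:
            config = np.zeros(n_cases, dtype=np.int64)
            for p in parents:  # sorted order, first most significant
                config = config * int(model.arities[p]) + (obs[:, p] - 1)
        u = rng.random(n_cases)
        cdf = np.cumsum(table, axis=1)
        obs[:, i] = 1 + (u[:, None] > cdf[config]).sum(axis=1)
    return DiscreteDataset(obs, model.arities.copy())


def generate_subjects(truth: Dag, config: ContinuousGenConfig) -> list[np.ndarray]:
    """Linear-Gaussian multi-subject series over a known network.

    Per subject, nodes are filled in topological order at each time point:
    ``x_j = strength * sum(parent values) + innovation + noise``, with
    standard-normal innovations and N(0, noise_sd) measurement noise, all
    contemporaneous (no lags).  Feed the result to
    :func:`immunedag.discretize.discretize_dataset`.
    """
    rng = np.random.default_rng(config.seed)
    order = _topological_order(truth)
    out = []
    for _s in range(config.n_subjects):
        mat = np.zeros((config.n_timepoints, truth.n_nodes))
        for j in order:
            signal = np.zeros(config.n_timepoints)
            for p in truth.parents_of(j):
                signal += mat[:, p]
            mat[:, j] = (
                config.connection_strength * signal
                + rng.standard_normal(config.n_timepoints)
                + config.noise_sd * rng.standard_normal(config.n_timepoints)
            )
        out.append(mat)
    return out
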