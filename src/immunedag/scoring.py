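"""The K2 structure score: the affinity that drives the immune search.

For a DAG G and discrete evidence the K2 metric is the Bayesian-Dirichlet
marginal likelihood with uniform (all-ones) Dirichlet parameter priors,

    P(G, Data) = P(G) * prod_i prod_j (r_i - 1)! / (N_ij + r_i - 1)!
                                      * prod_k N_ijk!,

where, for node X_i with parent set Pi(X_i), r_i is the node's arity, q_i the
number of parent configurations, N_ijk the number of cases with X_i at its
k-th value while Pi(X_i) sits in its j-th configuration, and
N_ij = sum_k N_ijk.  The structure prior P(G) is taken uniform and dropped;
everything here works on the natural log of the product, via log-gamma, and
larger is better.  The score decomposes over node families, so a per-family
memo makes rescoring after single-arc edits nearly free.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy.special import gammaln

from .discretize import DiscreteDataset
from .graph import Dag

__all__ = ["FamilyCounts", "family_counts", "family_log_score", "log_k2", "K2Scorer"]


@dataclass(frozen=True)
class FamilyCounts:
    """Sufficient statistics of one node family (child + ordered parent list).

    ``n_ijk`` has shape (q, r_child): rows are parent configurations in
    mixed-radix order (first listed parent most significant), columns child
    values; ``n_ij`` is its row sum.
    """

    child: int
    parents: tuple[int, ...]
    q: int
    n_ij: np.ndarray
    n_ijk: np.ndarray


def family_counts(
    data: DiscreteDataset, child: int, parents: Sequence[int]
) -> FamilyCounts:
    """Tabulate N_ijk / N_ij for one family over all cases of ``data``."""
    parents = tuple(int(p) for p in parents)
    n = data.n_nodes
    if not (0 <= child < n):
        raise ValueError(f"child {child} outside [0, {n})")
    for p in parents:
        if not (0 <= p < n):
            raise ValueError(f"parent {p} outside [0, {n})")
    if child in parents:
        raise ValueError(f"node {child} cannot be its own parent")
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parent in family")

    obs = data.observations
    r_child = int(data.arity[child])
    # mixed-radix configuration index, first parent most significant
    q = 1
    config = np.zeros(data.n_cases, dtype=np.int64)
    for p in parents:
        r_p = int(data.arity[p])
        config = config * r_p + (obs[:, p] - 1)
        q *= r_p
    joint = config * r_child + (obs[:, child] - 1)
    flat = np.bincount(joint, minlength=q * r_child)
    n_ijk = flat.reshape(q, r_child)
    return FamilyCounts(
        child=int(child),
        parents=parents,
        q=q,
        n_ij=n_ijk.sum(axis=1),
        n_ijk=n_ijk,
    )


def family_log_score(counts: FamilyCounts, r_child: int) -> float:
    """Log of the family's inner K2 product, via log-gamma.

    Per configuration j the term is
    ``lnGamma(r) - lnGamma(N_ij + r) + sum_k lnGamma(N_ijk + 1)`` with
    r = r_child; empty configurations contribute exactly 0.
    """
    r = int(r_child)
    n_ij = np.asarray(counts.n_ij, dtype=float)
    n_ijk = np.asarray(counts.n_ijk, dtype=float)
    term = gammaln(r) - gammaln(n_ij + r) + gammaln(n_ijk + 1.0).sum(axis=1)
    return float(term.sum())


class K2Scorer:
    """Log-K2 evaluator for one dataset with a per-family memo.

    The memo keys on (child, sorted parent tuple); parent order only permutes
    configuration rows and leaves the score unchanged.
    """

    def __init__(self, data: DiscreteDataset):
        self.data = data
        self._memo: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_score(self, child: int, parents: Sequence[int]) -> float:
        key = (int(child), tuple(sorted(int(p) for p in parents)))
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        counts = family_counts(self.data, key[0], key[1])
        score = family_log_score(counts, int(self.data.arity[key[0]]))
        self._memo[key] = score
        return score

    def add_arc_gain(self, dag: Dag, i: int, j: int) -> float:
        """Score change from adding i -> j (only node j's family changes)."""
        parents = dag.parents_of(j)
        return self.family_score(j, parents + (i,)) - self.family_score(j, parents)

    def log_score(self, dag: Dag) -> float:
        if dag.n_nodes != self.data.n_nodes:
            raise ValueError(
                f"graph has {dag.n_nodes} nodes but data has {self.data.n_nodes}"
            )
        return sum(self.family_score(i, dag.parents_of(i)) for i in range(dag.n_nodes))


def log_k2(dag: Dag, data: DiscreteDataset, scorer: K2Scorer | None = None) -> float:
    """Natural-log K2 affinity of ``dag`` on ``data`` (uniform structure prior).

    Pass an existing :class:`K2Scorer` to reuse its family memo across many
    evaluations on the same dataset.
    """
    if scorer is None:
        scorer = K2Scorer(data)
    elif scorer.data is not data:
        raise ValueError("scorer was built for a different dataset")
    return scorer.log_score(dag)
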