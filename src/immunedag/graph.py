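"""Directed acyclic graphs and the safe structural edits the search operators use.

A :class:`Dag` is the genotype of every candidate network: a fixed node set
``0..n_nodes-1`` (one node per brain region / ROI) plus a set of directed arcs
``(i, j)`` meaning "node i causally influences node j".  Instances are
immutable; every edit returns a fresh graph, so candidates can be shared
between populations without defensive copying.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from typing import Optional

__all__ = [
    "Dag",
    "is_acyclic",
    "try_add_arc",
    "delete_arc",
    "try_reverse_arc",
    "incident_arcs",
    "enumerate_all_dags",
]

Arc = tuple[int, int]


def _check_arcs(n_nodes: int, arcs: Iterable[Arc]) -> frozenset[Arc]:
    out = frozenset((int(i), int(j)) for i, j in arcs)
    for i, j in out:
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValueError(f"arc ({i}, {j}) references a node outside [0, {n_nodes})")
        if i == j:
            raise ValueError(f"self-arc ({i}, {i}) is not allowed")
    return out


def is_acyclic(n_nodes: int, arcs: Iterable[Arc]) -> bool:
    """True iff the arc set admits a topological ordering (Kahn's algorithm)."""
    arcset = _check_arcs(n_nodes, arcs)
    indeg = [0] * n_nodes
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for i, j in arcset:
        indeg[j] += 1
        children[i].append(j)
    queue = [v for v in range(n_nodes) if indeg[v] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for w in children[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == n_nodes


class Dag:
    """Immutable labelled DAG: ``n_nodes`` nodes, ``arcs`` a frozenset of (tail, head)."""

    __slots__ = ("n_nodes", "arcs", "_parents", "_children")

    def __init__(self, n_nodes: int, arcs: Iterable[Arc] = ()):
        n_nodes = int(n_nodes)
        if n_nodes < 1:
            raise ValueError("a Dag needs at least one node")
        arcset = _check_arcs(n_nodes, arcs)
        if not is_acyclic(n_nodes, arcset):
            raise ValueError("arc set contains a directed cycle")
        object.__setattr__(self, "n_nodes", n_nodes)
        object.__setattr__(self, "arcs", arcset)
        object.__setattr__(self, "_parents", None)
        object.__setattr__(self, "_children", None)

    @classmethod
    def _unsafe(cls, n_nodes: int, arcs: frozenset[Arc]) -> "Dag":
        """Internal constructor for arc sets already known to be valid DAGs."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "n_nodes", n_nodes)
        object.__setattr__(obj, "arcs", arcs)
        object.__setattr__(obj, "_parents", None)
        object.__setattr__(obj, "_children", None)
        return obj

    def __setattr__(self, name, value):  # pragma: no cover - guard
        raise AttributeError("Dag is immutable")

    # -- adjacency -----------------------------------------------------
    def _adjacency(self) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
        if self._parents is None:
            parents: list[list[int]] = [[] for _ in range(self.n_nodes)]
            children: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, j in self.arcs:
                parents[j].append(i)
                children[i].append(j)
            object.__setattr__(self, "_parents", [tuple(sorted(p)) for p in parents])
            object.__setattr__(self, "_children", [tuple(sorted(c)) for c in children])
        return self._parents, self._children

    def parents_of(self, j: int) -> tuple[int, ...]:
        self._check_node(j)
        return self._adjacency()[0][j]

    def children_of(self, i: int) -> tuple[int, ...]:
        self._check_node(i)
        return self._adjacency()[1][i]

    def has_arc(self, i: int, j: int) -> bool:
        return (i, j) in self.arcs

    def _check_node(self, v: int) -> None:
        if not (0 <= v < self.n_nodes):
            raise ValueError(f"node {v} outside [0, {self.n_nodes})")

    def reaches(self, a: int, b: int) -> bool:
        """True iff a directed path a -> ... -> b exists (a == b counts)."""
        if a == b:
            return True
        _, children = self._adjacency()
        stack = [a]
        seen = {a}
        while stack:
            v = stack.pop()
            for w in children[v]:
                if w == b:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    # -- dunder --------------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dag)
            and self.n_nodes == other.n_nodes
            and self.arcs == other.arcs
        )

    def __hash__(self) -> int:
        return hash((self.n_nodes, self.arcs))

    def __repr__(self) -> str:
        arcs = sorted(self.arcs)
        return f"Dag(n_nodes={self.n_nodes}, arcs={arcs})"


def try_add_arc(dag: Dag, i: int, j: int) -> Optional[Dag]:
    """Add i -> j if that keeps the graph acyclic; return None on cycle rejection.

    Raises ``ValueError`` for the distinct *invalid request* cases (self-arc,
    arc already present, bad index); an acyclicity rejection is a normal
    outcome, signalled by ``None``.
    """
    dag._check_node(i)
    dag._check_node(j)
    if i == j:
        raise ValueError("cannot add a self-arc")
    if (i, j) in dag.arcs:
        raise ValueError(f"arc ({i}, {j}) already present")
    # i -> j closes a cycle iff j already reaches i
    if dag.reaches(j, i):
        return None
    return Dag._unsafe(dag.n_nodes, dag.arcs | {(i, j)})


def delete_arc(dag: Dag, i: int, j: int) -> Dag:
    """Remove the present arc i -> j (deletion can never create a cycle)."""
    if (i, j) not in dag.arcs:
        raise ValueError(f"arc ({i}, {j}) not present")
    return Dag._unsafe(dag.n_nodes, dag.arcs - {(i, j)})


def try_reverse_arc(dag: Dag, i: int, j: int) -> Optional[Dag]:
    """Replace i -> j with j -> i if the result is still a DAG; None otherwise."""
    if (i, j) not in dag.arcs:
        raise ValueError(f"arc ({i}, {j}) not present")
    without = dag.arcs - {(i, j)}
    stripped = Dag._unsafe(dag.n_nodes, without)
    # j -> i closes a cycle iff i still reaches j through another path
    if stripped.reaches(i, j):
        return None
    return Dag._unsafe(dag.n_nodes, without | {(j, i)})


def incident_arcs(dag: Dag, i: int) -> frozenset[Arc]:
    """All arcs whose head or tail is node i (the neighbourhood a crossover swaps)."""
    dag._check_node(i)
    return frozenset(a for a in dag.arcs if a[0] == i or a[1] == i)


def enumerate_all_dags(n_nodes: int) -> Iterator[Dag]:
    """Yield every labelled DAG on ``n_nodes`` nodes exactly once (n_nodes <= 5).

    Exhaustive recursion over the n(n-1) ordered pairs with incremental cycle
    pruning; counts follow the labelled-DAG sequence 1, 3, 25, 543, 29281.
    Serves as the ground-truth search space for small-n certification.
    """
    n_nodes = int(n_nodes)
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    if n_nodes > 5:
        raise ValueError("exhaustive DAG enumeration is limited to n_nodes <= 5")
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]

    def rec(idx: int, current: Dag) -> Iterator[Dag]:
        if idx == len(pairs):
            yield current
            return
        i, j = pairs[idx]
        yield from rec(idx + 1, current)
        if (j, i) not in current.arcs:
            added = try_add_arc(current, i, j)
            if added is not None:
                yield from rec(idx + 1, added)

    yield from rec(0, Dag(n_nodes))
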