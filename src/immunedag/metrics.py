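"""Structural comparison of a learned DAG against ground truth.

Two views of agreement are scored.  *Connections* ignore orientation: an
unordered node pair counts as shared (C_s) when both graphs connect it and as
added (C_a) when only the learned network does; TC is the truth's connection
total.  *Directions* respect orientation: D_s arcs match exactly, D_w share
the connection but point the wrong way, D_a are the arcs carried by the C_a
added connections, and TD is the truth's arc total.  Precision, recall and
F-measure are then

    Precision_c = C_s / (C_a + C_s)        Recall_c = C_s / TC
    Precision_d = D_s / (D_w + D_a + D_s)  Recall_d = D_s / TD

with F the harmonic mean of its pair and F defined as 0 whenever both
components are 0.  Counts may be fractional: averages over repeated runs are
formed by averaging counts first and applying the formulas once.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable

from .graph import Dag

__all__ = ["EvalCounts", "MetricSet", "compare_structures", "compute_metrics", "mean_counts"]


@dataclass(frozen=True)
class EvalCounts:
    """Structure-difference tallies between a learned and a truth network.

    Fractional values are allowed (averages over runs).
    """

    c_a: float  # connections only in the learned network
    c_s: float  # connections shared (orientation ignored)
    d_w: float  # shared connections pointing the wrong way
    d_a: float  # extra arcs carried by the c_a added connections
    d_s: float  # arcs identical in both networks
    tc: float  # total connections in truth
    td: float  # total arcs in truth

    def __post_init__(self):
        for name in ("c_a", "c_s", "d_w", "d_a", "d_s", "tc", "td"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    precision_c: float
    recall_c: float
    f_c: float
    precision_d: float
    recall_d: float
    f_d: float


def compare_structures(learned: Dag, truth: Dag) -> EvalCounts:
    """Tally connection and direction differences between two DAGs."""
    if learned.n_nodes != truth.n_nodes:
        raise ValueError(
            f"node counts differ: learned {learned.n_nodes}, truth {truth.n_nodes}"
        )
    learned_conn = {frozenset(a) for a in learned.arcs}
    truth_conn = {frozenset(a) for a in truth.arcs}
    shared_conn = learned_conn & truth_conn
    c_s = len(shared_conn)
    c_a = len(learned_conn - truth_conn)
    d_s = sum(1 for a in learned.arcs if a in truth.arcs and frozenset(a) in shared_conn)
    return EvalCounts(
        c_a=c_a,
        c_s=c_s,
        d_w=c_s - d_s,
        d_a=c_a,  # a DAG carries exactly one arc per added connection
        d_s=d_s,
        tc=len(truth.arcs),
        td=len(truth.arcs),
    )


def _f_measure(precision: float, recall: float) -> float:
    if precision == 0 and recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_metrics(counts: EvalCounts) -> MetricSet:
    """Precision / recall / F for connections and directions from the tallies."""
    if counts.tc <= 0 or counts.td <= 0:
        raise ValueError("metrics are undefined for an empty ground-truth network")
    conn_den = counts.c_a + counts.c_s
    precision_c = counts.c_s / conn_den if conn_den > 0 else 0.0
    recall_c = counts.c_s / counts.tc
    dir_den = counts.d_w + counts.d_a + counts.d_s
    precision_d = counts.d_s / dir_den if dir_den > 0 else 0.0
    recall_d = counts.d_s / counts.td
    return MetricSet(
        precision_c=precision_c,
        recall_c=recall_c,
        f_c=_f_measure(precision_c, recall_c),
        precision_d=precision_d,
        recall_d=recall_d,
        f_d=_f_measure(precision_d, recall_d),
    )


def mean_counts(all_counts: Iterable[EvalCounts]) -> EvalCounts:
    """Average tallies over repeated runs (yields fractional counts)."""
    items = list(all_counts)
    if not items:
        raise ValueError("no counts to average")
    n = len(items)
    return EvalCounts(
        c_a=sum(c.c_a for c in items) / n,
        c_s=sum(c.c_s for c in items) / n,
        d_w=sum(c.d_w for c in items) / n,
        d_a=sum(c.d_a for c in items) / n,
        d_s=sum(c.d_s for c in items) / n,
        tc=sum(c.tc for c in items) / n,
        td=sum(c.td for c in items) / n,
    )
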