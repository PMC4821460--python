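"""Plain-text exchange formats: edge lists and delimited subject matrices.

Edge lists are tab-separated ``tail<TAB>head`` pairs with 1-based node labels
and an optional ``# n_nodes=K`` header; node indices are 0-based everywhere
inside the package and converted only here, at the boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .discretize import DiscreteDataset
from .graph import Dag

__all__ = ["read_edge_list", "write_edge_list", "load_subject_table", "write_dataset_tsv", "read_dataset_tsv"]


def write_edge_list(dag: Dag, path) -> None:
    lines = [f"# n_nodes={dag.n_nodes}"]
    lines += [f"{i + 1}\t{j + 1}" for i, j in sorted(dag.arcs)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path) -> Dag:
    n_nodes = None
    arcs = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("n_nodes="):
                n_nodes = int(body.split("=", 1)[1])
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"malformed edge-list line: {raw!r}")
        tail, head = int(fields[0]), int(fields[1])
        if tail < 1 or head < 1:
            raise ValueError(f"edge-list labels are 1-based, got {raw!r}")
        arcs.append((tail - 1, head - 1))
    if n_nodes is None:
        n_nodes = max((max(a) for a in arcs), default=-1) + 1
        if n_nodes == 0:
            raise ValueError("empty edge list without an '# n_nodes=' header")
    return Dag(n_nodes, arcs)


def load_subject_table(path) -> np.ndarray:
    """One delimited text file per subject, rows = time points, columns = nodes.

    The delimiter (tab, comma, whitespace) is sniffed; a single non-numeric
    first row is treated as a header.  Missing values are rejected.
    """
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    df = pd.read_csv(_io.StringIO(text), sep=sep, header=None, engine="python")
    if df.shape[0] and df.iloc[0].map(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    mat = df.to_numpy(dtype=float)
    if mat.size == 0:
        raise ValueError(f"{path}: empty subject matrix")
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"{path}: non-finite or missing values")
    return mat


def write_dataset_tsv(data: DiscreteDataset, path) -> None:
    header = "\t".join(f"node{i + 1}" for i in range(data.n_nodes))
    body = "\n".join("\t".join(str(v) for v in row) for row in data.observations)
    Path(path).write_text(header + "\n" + body + "\n")


def read_dataset_tsv(path) -> DiscreteDataset:
    df = pd.read_csv(path, sep="\t")
    obs = df.to_numpy(dtype=np.int64)
    return DiscreteDataset(obs, obs.max(axis=0))
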