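"""File input/output: expression matrices, network writers, run manifests.

Expression files are delimited text (comma or tab, sniffed) with a header
line and a leading identifier column; the omics convention of features in
rows is the default orientation.  Networks are written as TSV edge lists
(exact round trip), SIF for Cytoscape, and GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data import ConditionPair
from .network import Edge, DifferentialNetwork

__all__ = [
    "read_expression",
    "load_condition_pair",
    "write_networks",
    "read_network_tsv",
    "read_truth_tsv",
    "write_manifest",
]

_SIF_RELATION = {
    "common": "common",
    "condition1_only": "cond1",
    "condition2_only": "cond2",
    "differential_weight": "diffweight",
}
_SIF_CLASS = {v: k for k, v in _SIF_RELATION.items()}


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(
    path: str | Path, orientation: str = "features_in_rows"
) -> tuple[np.ndarray, list[str]]:
    """Read a numeric matrix; returns (samples x features array, feature
    names).  Non-numeric cells and duplicate identifiers are rejected with
    the offending location named."""
    if orientation not in ("features_in_rows", "features_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path.name}: non-numeric or missing value at row "
            f"'{df.index[r]}', column '{df.columns[c]}'"
        )
    if orientation == "features_in_rows":
        features = [str(x) for x in df.index]
        matrix = numeric.values.T
    else:
        features = [str(x) for x in df.columns]
        matrix = numeric.values
    if len(set(features)) != len(features):
        raise ValueError(f"{path.name}: duplicate feature identifiers")
    return np.asarray(matrix, dtype=float), features


def load_condition_pair(
    path1: str | Path, path2: str | Path, orientation: str = "features_in_rows"
) -> ConditionPair:
    """Load both condition files; condition-2 columns are matched by feature
    name and reordered to the condition-1 (canonical) order."""
    X1, feats1 = read_expression(path1, orientation)
    X2, feats2 = read_expression(path2, orientation)
    if set(feats1) != set(feats2):
        missing = sorted(set(feats1) ^ set(feats2))[:5]
        raise ValueError(f"feature sets differ between conditions (e.g. {missing})")
    order = [feats2.index(f) for f in feats1]
    return ConditionPair(feats1, X1, X2[:, order], standardized=False)


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest exact round-trip decimal


def write_networks(
    net: DifferentialNetwork,
    prefix: str | Path,
    formats: tuple[str, ...] = ("tsv",),
) -> dict[str, Path]:
    """Write the network in the requested formats; returns written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "tsv":
            path = prefix.with_name(prefix.name + "_edges.tsv")
            with open(path, "w") as fh:
                fh.write("# nodes=" + ",".join(net.nodes) + "\n")
                fh.write("# symmetrization=" + net.symmetrization + "\n")
                fh.write("node_a\tnode_b\tbeta1\tbeta2\tedge_class\n")
                for e in net.edges:
                    fh.write(
                        f"{e.node_a}\t{e.node_b}\t{_fmt(e.beta1)}\t"
                        f"{_fmt(e.beta2)}\t{e.edge_class}\n"
                    )
        elif fmt == "sif":
            path = prefix.with_name(prefix.name + ".sif")
            with open(path, "w") as fh:
                for e in net.edges:
                    fh.write(f"{e.node_a}\t{_SIF_RELATION[e.edge_class]}\t{e.node_b}\n")
        elif fmt == "graphml":
            path = prefix.with_name(prefix.name + ".graphml")
            g = nx.Graph(symmetrization=net.symmetrization)
            g.add_nodes_from(net.nodes)
            for e in net.edges:
                g.add_edge(
                    e.node_a, e.node_b,
                    beta1=e.beta1, beta2=e.beta2, edge_class=e.edge_class,
                )
            nx.write_graphml(g, path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths[fmt] = path
    return paths


def read_network_tsv(path: str | Path) -> DifferentialNetwork:
    """Exact inverse of the TSV writer."""
    path = Path(path)
    nodes: tuple[str, ...] = ()
    symmetrization = "or_rule"
    edges: list[Edge] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# nodes="):
                nodes = tuple(line[len("# nodes="):].split(","))
                continue
            if line.startswith("# symmetrization="):
                symmetrization = line[len("# symmetrization="):]
                continue
            if line.startswith("node_a") or not line:
                continue
            a, b, b1, b2, cls = line.split("\t")
            edges.append(Edge(a, b, float(b1), float(b2), cls))
    if not nodes:
        raise ValueError(f"{path.name}: missing '# nodes=' header")
    return DifferentialNetwork(nodes, tuple(edges), symmetrization)


def read_truth_tsv(
    path: str | Path,
) -> tuple[tuple[str, ...], dict[str, set[tuple[str, str]]]]:
    """Read a ground-truth edge-label TSV (node_a, node_b, label in
    {common, cond1, cond2}); returns (nodes, label -> name-pair sets)."""
    path = Path(path)
    nodes: tuple[str, ...] = ()
    sets: dict[str, set[tuple[str, str]]] = {"common": set(), "cond1": set(), "cond2": set()}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# nodes="):
                nodes = tuple(line[len("# nodes="):].split(","))
                continue
            if line.startswith("node_a") or line.startswith("#") or not line:
                continue
            a, b, label = line.split("\t")
            if label not in sets:
                raise ValueError(f"{path.name}: unknown truth label {label!r}")
            sets[label].add((a, b))
    if not nodes:
        raise ValueError(f"{path.name}: missing '# nodes=' header")
    return nodes, sets


def write_manifest(path: str | Path, payload: dict) -> Path:
    """Write the machine-readable run manifest."""
    import fusedggm

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(payload)
    payload.setdefault("versions", {})
    payload["versions"].update(
        {"fusedggm": fusedggm.__version__, "numpy": np.__version__}
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
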