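"""Ground-truth-embedded two-condition data simulator.

The generator builds a sparse precision matrix with one of four support
topologies (random, cluster, hub, scale_free — the latter two organized in
modules), optionally rewires a fraction of its edges to create the
condition-2 truth, and samples Gaussian (or, for robustness studies,
multivariate-t) data from both precision matrices.

Positive definiteness is enforced by construction: off-diagonal entries are
drawn uniformly from ``edge_weight_range`` with random sign and the diagonal
is set to the row-wise absolute off-diagonal sum plus a 0.1 margin, so every
generated matrix is strictly diagonally dominant.  Rewiring removes and adds
the same number of edges, keeping density identical between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import networkx as nx
import numpy as np

from .data import ConditionPair

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_network",
    "rewire",
    "sample_data",
    "simulate_study",
    "write_fixture",
]

NETWORK_TYPES = ("random", "cluster", "hub", "scale_free")
DIAGONAL_MARGIN = 0.1


@dataclass(frozen=True)
class SimulationSpec:
    network_type: str
    p: int
    n1: int
    n2: int
    n_modules: int = 1
    rewire_fraction: float = 0.0
    edge_weight_range: tuple[float, float] = (0.2, 0.6)
    edge_prob: float | None = None  # random topology; default 3/(p-1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network_type not in NETWORK_TYPES:
            raise ValueError(f"unknown network_type {self.network_type!r}")
        if self.p < 10:
            raise ValueError("need p >= 10")
        if not (0.0 <= self.rewire_fraction <= 1.0):
            raise ValueError("rewire_fraction must lie in [0, 1]")
        if self.network_type in ("cluster", "scale_free") and self.p % self.n_modules:
            raise ValueError("n_modules must divide p for cluster/scale_free")
        lo, hi = self.edge_weight_range
        if not (0 < lo <= hi):
            raise ValueError("edge_weight_range must be positive and ordered")


@dataclass(frozen=True)
class GroundTruth:
    """Precision matrices for both conditions plus derived edge labels."""

    omega1: np.ndarray
    omega2: np.ndarray

    def __post_init__(self) -> None:
        for name, om in (("omega1", self.omega1), ("omega2", self.omega2)):
            if not np.allclose(om, om.T):
                raise ValueError(f"{name} is not symmetric")
            if np.linalg.eigvalsh(om).min() <= 1e-8:
                raise ValueError(f"{name} is not positive definite")

    @property
    def p(self) -> int:
        return self.omega1.shape[0]

    @staticmethod
    def _support(om: np.ndarray) -> frozenset[tuple[int, int]]:
        i, j = np.nonzero(np.triu(om, k=1))
        return frozenset(zip(i.tolist(), j.tolist()))

    @cached_property
    def support1(self) -> frozenset[tuple[int, int]]:
        return self._support(self.omega1)

    @cached_property
    def support2(self) -> frozenset[tuple[int, int]]:
        return self._support(self.omega2)

    @cached_property
    def common_edges(self) -> frozenset[tuple[int, int]]:
        return self.support1 & self.support2

    @cached_property
    def diff_edges(self) -> frozenset[tuple[int, int]]:
        return self.support1 ^ self.support2


def _support_graph(spec: SimulationSpec, rng: np.random.Generator) -> nx.Graph:
    p = spec.p
    gseed = int(rng.integers(0, 2**31 - 1))
    if spec.network_type == "random":
        prob = spec.edge_prob if spec.edge_prob is not None else 3.0 / (p - 1)
        return nx.erdos_renyi_graph(p, prob, seed=gseed)
    if spec.network_type == "cluster":
        # dense within-module blocks, no between-module edges
        m = p // spec.n_modules
        g = nx.Graph()
        g.add_nodes_from(range(p))
        for b in range(spec.n_modules):
            nodes = range(b * m, (b + 1) * m)
            sub = nx.erdos_renyi_graph(m, 0.25, seed=gseed + b)
            g.add_edges_from(
                (b * m + u, b * m + v) for u, v in sub.edges
            )
        return g
    if spec.network_type == "hub":
        # a few high-degree nodes over a sparse matched background
        n_hubs = max(1, p // 20)
        k_hub = max(4, p // 4)
        g = nx.Graph()
        g.add_nodes_from(range(p))
        non_hubs = np.arange(n_hubs, p)
        for h in range(n_hubs):
            partners = rng.choice(non_hubs, size=min(k_hub, non_hubs.size),
                                  replace=False)
            g.add_edges_from((h, int(t)) for t in partners)
        shuffled = rng.permutation(non_hubs)
        for a, b in zip(shuffled[::2], shuffled[1::2]):
            g.add_edge(int(a), int(b))
        return g
    # scale_free: preferential attachment within each module
    m = p // spec.n_modules
    if m < 3:
        raise ValueError("scale_free modules need at least 3 nodes")
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for b in range(spec.n_modules):
        sub = nx.barabasi_albert_graph(m, 1, seed=gseed + b)
        g.add_edges_from((b * m + u, b * m + v) for u, v in sub.edges)
    return g


def _precision_from_support(
    edges: list[tuple[int, int]],
    p: int,
    weight_range: tuple[float, float],
    rng: np.random.Generator,
    weights: dict[tuple[int, int], float] | None = None,
) -> np.ndarray:
    lo, hi = weight_range
    om = np.zeros((p, p))
    for (i, j) in edges:
        if weights is not None and (i, j) in weights:
            w = weights[(i, j)]
        else:
            w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        om[i, j] = om[j, i] = w
    np.fill_diagonal(om, np.abs(om).sum(axis=1) + DIAGONAL_MARGIN)
    return om


def make_network(spec: SimulationSpec) -> GroundTruth:
    """Build the condition-1 precision matrix; condition 2 starts identical
    (null hypothesis).  Apply :func:`rewire` for a non-null truth."""
    rng = np.random.default_rng(spec.seed)
    g = _support_graph(spec, rng)
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges)
    if not edges:
        raise ValueError("generated support has no edges; raise density or p")
    if len(edges) >= spec.p * (spec.p - 1) // 2:
        raise ValueError("complete support cannot be rewired; lower the density")
    omega1 = _precision_from_support(edges, spec.p, spec.edge_weight_range, rng)
    return GroundTruth(omega1, omega1.copy())


def rewire(
    truth: GroundTruth,
    rewire_fraction: float,
    seed: int,
    weight_range: tuple[float, float] = (0.2, 0.6),
) -> GroundTruth:
    """Replace ``round(fraction * |edges|)`` condition-1 edges with the same
    number of new edges to form the condition-2 precision matrix.

    Kept edges retain their condition-1 weights, so every surviving edge is
    a ground-truth common edge and the support difference is exactly the
    rewired set.  The diagonal is rebuilt, preserving positive definiteness.
    """
    rng = np.random.default_rng(seed)
    p = truth.p
    edges = sorted(truth.support1)
    n_rewire = round(rewire_fraction * len(edges))
    if n_rewire == 0:
        return GroundTruth(truth.omega1, truth.omega1.copy())
    all_pairs = {(i, j) for i in range(p) for j in range(i + 1, p)}
    non_edges = sorted(all_pairs - set(edges))
    if n_rewire > len(non_edges):
        raise ValueError("not enough absent pairs to rewire into")
    weights = {
        (i, j): truth.omega1[i, j] for (i, j) in edges
    }
    for attempt in range(100):
        drop_idx = rng.choice(len(edges), size=n_rewire, replace=False)
        add_idx = rng.choice(len(non_edges), size=n_rewire, replace=False)
        dropped = {edges[k] for k in drop_idx}
        kept = [e for e in edges if e not in dropped]
        added = [non_edges[k] for k in add_idx]
        omega2 = _precision_from_support(
            kept + added, p, weight_range, rng, weights=weights
        )
        if np.linalg.eigvalsh(omega2).min() > 1e-8:
            return GroundTruth(truth.omega1, omega2)
    raise RuntimeError("could not maintain positive definiteness after 100 redraws")


def sample_data(
    truth: GroundTruth,
    n1: int,
    n2: int,
    seed: int,
    t_dof: float | None = None,
    feature_prefix: str = "f",
) -> ConditionPair:
    """Draw ``n1`` and ``n2`` zero-mean samples with covariance
    ``inv(omega_k)``.  With ``t_dof`` set, draws come from a multivariate t
    with that many degrees of freedom instead (heavy-tail robustness
    checks); the Gaussian is the ``t_dof=None`` default."""
    rng = np.random.default_rng(seed)
    p = truth.p
    xs = []
    for om, n in ((truth.omega1, n1), (truth.omega2, n2)):
        cov = np.linalg.inv(om)
        L = np.linalg.cholesky(cov)
        X = rng.standard_normal((n, p)) @ L.T
        if t_dof is not None:
            scale = np.sqrt(rng.chisquare(t_dof, size=n) / t_dof)
            X = X / scale[:, None]
        xs.append(X)
    features = [f"{feature_prefix}{i:03d}" for i in range(p)]
    return ConditionPair(features, xs[0], xs[1], standardized=False)


def simulate_study(spec: SimulationSpec) -> tuple[GroundTruth, ConditionPair]:
    """One-call study: build truth, rewire, sample.  All randomness derives
    from ``spec.seed``."""
    truth = make_network(spec)
    if spec.rewire_fraction > 0:
        truth = rewire(truth, spec.rewire_fraction, spec.seed + 1,
                       weight_range=spec.edge_weight_range)
    pair = sample_data(truth, spec.n1, spec.n2, spec.seed + 2)
    return truth, pair


_LABELS = {"common": "common", "cond1": "cond1", "cond2": "cond2"}


def write_fixture(
    truth: GroundTruth, pair: ConditionPair, prefix: str | Path
) -> dict[str, Path]:
    """Write the CSV dialect the CLI reads (features in rows) plus a
    ground-truth edge-label TSV (node_a, node_b, label)."""
    import pandas as pd

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, X, n in (("data1", pair.X1, pair.n1), ("data2", pair.X2, pair.n2)):
        df = pd.DataFrame(
            X.T, index=list(pair.features),
            columns=[f"s{k}" for k in range(n)],
        )
        path = prefix.with_name(prefix.name + f"_{tag}.csv")
        df.to_csv(path)
        paths[tag] = path
    rows = []
    for (i, j) in sorted(truth.common_edges):
        rows.append((pair.features[i], pair.features[j], "common"))
    for (i, j) in sorted(truth.diff_edges):
        label = "cond1" if (i, j) in truth.support1 else "cond2"
        rows.append((pair.features[i], pair.features[j], label))
    tpath = prefix.with_name(prefix.name + "_truth.tsv")
    with open(tpath, "w") as fh:
        fh.write("# nodes=" + ",".join(pair.features) + "\n")
        fh.write("node_a\tnode_b\tlabel\n")
        for a, b, lab in rows:
            fh.write(f"{a}\t{b}\t{lab}\n")
    paths["truth"] = tpath
    return paths
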