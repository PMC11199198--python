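"""Assemble per-node neighborhood solutions into an undirected network.

Neighborhood selection yields two directed opinions per feature pair
(i regressed on j, and j on i).  Symmetrization turns them into one
undirected edge per pair:

``or_rule``
    the edge exists in condition *k* when either direction's coefficient is
    nonzero; the reported per-condition weight is the maximum-magnitude
    direction's coefficient (sensitivity-oriented; the default).
``and_rule``
    both directions must be nonzero in condition *k*; the weight is the mean
    of the two directions (specificity-oriented).

Because the fused penalty produces exact coefficient equality and exact
zeros, edge classification is tolerance-free: ``common`` means
``beta1 == beta2 != 0`` bitwise, condition-specific means the other
condition's weight is exactly zero, and ``differential_weight`` means both
nonzero but unequal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ConditionPair, RegularizationPair
from .solver import SolverState, coefficient_matrices, solve_all_nodes

__all__ = [
    "Edge",
    "DifferentialNetwork",
    "assemble",
    "assemble_from_matrices",
    "differential_edges",
    "common_edges",
    "fit_differential_network",
]

EDGE_CLASSES = ("common", "condition1_only", "condition2_only", "differential_weight")


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    beta1: float
    beta2: float
    edge_class: str


@dataclass(frozen=True)
class DifferentialNetwork:
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    symmetrization: str = "or_rule"

    def __post_init__(self) -> None:
        order = {n: i for i, n in enumerate(self.nodes)}
        for e in self.edges:
            if order[e.node_a] >= order[e.node_b]:
                raise ValueError(f"edge {e.node_a}-{e.node_b} not in node order")
            if e.edge_class not in EDGE_CLASSES:
                raise ValueError(f"unknown edge class {e.edge_class!r}")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edge_index_pairs(self) -> dict[tuple[int, int], Edge]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return {(order[e.node_a], order[e.node_b]): e for e in self.edges}


def _classify(beta1: float, beta2: float) -> str | None:
    if beta1 == 0.0 and beta2 == 0.0:
        return None
    if beta2 == 0.0:
        return "condition1_only"
    if beta1 == 0.0:
        return "condition2_only"
    if beta1 == beta2:
        return "common"
    return "differential_weight"


def assemble_from_matrices(
    B1: np.ndarray,
    B2: np.ndarray,
    features: tuple[str, ...] | list[str],
    rule: str = "or_rule",
) -> DifferentialNetwork:
    """Symmetrize coefficient matrices ``B_k[i, j]`` (predictor j in node i's
    regression) into an undirected classified edge list."""
    if rule not in ("or_rule", "and_rule"):
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    p = len(features)
    if B1.shape != (p, p) or B2.shape != (p, p):
        raise ValueError("coefficient matrices inconsistent with node count")
    edges: list[Edge] = []
    for i in range(p):
        for j in range(i + 1, p):
            betas = []
            for B in (B1, B2):
                lo, hi = B[i, j], B[j, i]  # i<-j and j<-i directions
                if rule == "or_rule":
                    if lo == 0.0 and hi == 0.0:
                        betas.append(0.0)
                    else:
                        # |beta| tie broken toward the lower-index response row
                        betas.append(lo if abs(lo) >= abs(hi) else hi)
                else:  # and_rule
                    betas.append(0.5 * (lo + hi) if lo != 0.0 and hi != 0.0 else 0.0)
            cls = _classify(betas[0], betas[1])
            if cls is not None:
                edges.append(Edge(features[i], features[j], betas[0], betas[1], cls))
    return DifferentialNetwork(tuple(features), tuple(edges), rule)


def assemble(
    neighborhoods: list[SolverState],
    features: tuple[str, ...] | list[str],
    rule: str = "or_rule",
) -> DifferentialNetwork:
    """Assemble the per-node solver states into a differential network."""
    p = len(features)
    if len(neighborhoods) != p:
        raise ValueError(
            f"got {len(neighborhoods)} neighborhoods for {p} nodes"
        )
    B1, B2 = coefficient_matrices(neighborhoods, p)
    return assemble_from_matrices(B1, B2, features, rule)


def differential_edges(net: DifferentialNetwork) -> list[Edge]:
    """Edges whose presence or strength differs between conditions."""
    return [e for e in net.edges if e.edge_class != "common"]


def common_edges(net: DifferentialNetwork) -> list[Edge]:
    return [e for e in net.edges if e.edge_class == "common"]


def fit_differential_network(
    pair: ConditionPair,
    reg: RegularizationPair,
    rule: str = "or_rule",
    **solver_kwargs,
) -> DifferentialNetwork:
    """Convenience wrapper: solve every node and assemble the network."""
    states = solve_all_nodes(pair, reg, **solver_kwargs)
    return assemble(states, pair.features, rule)
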