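"""Core data model for two-condition network learning.

A study is represented as a :class:`ConditionPair`: two feature-aligned
sample-by-feature matrices, one per biological condition.  Network learning
proceeds by neighborhood selection — for every feature (node) a sparse
regression of that feature on all others is solved jointly across the two
conditions; :class:`NodeRegressionProblem` packages one such regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConditionPair",
    "NodeRegressionProblem",
    "CoefficientPair",
    "RegularizationPair",
    "standardize",
    "build_node_problem",
]


@dataclass(frozen=True)
class ConditionPair:
    """Feature-aligned data matrices for two conditions.

    Parameters
    ----------
    features:
        Ordered feature identifiers shared by both matrices.
    X1, X2:
        Arrays of shape ``(N1, p)`` and ``(N2, p)`` (samples in rows).
    standardized:
        True when every column of each matrix has mean 0 and unit
        (population) variance within its own condition.
    """

    features: tuple[str, ...]
    X1: np.ndarray
    X2: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        X1 = np.asarray(self.X1, dtype=float)
        X2 = np.asarray(self.X2, dtype=float)
        object.__setattr__(self, "features", tuple(str(f) for f in self.features))
        object.__setattr__(self, "X1", X1)
        object.__setattr__(self, "X2", X2)
        p = len(self.features)
        if p < 2:
            raise ValueError("need at least 2 features")
        if X1.ndim != 2 or X2.ndim != 2:
            raise ValueError("data matrices must be 2-D (samples x features)")
        if X1.shape[1] != p or X2.shape[1] != p:
            raise ValueError(
                f"feature count mismatch: {p} names vs matrices "
                f"{X1.shape[1]} / {X2.shape[1]}"
            )
        if X1.shape[0] < 2 or X2.shape[0] < 2:
            raise ValueError("each condition needs at least 2 samples")
        for name, X in (("condition 1", X1), ("condition 2", X2)):
            if not np.all(np.isfinite(X)):
                raise ValueError(f"{name} matrix contains missing/non-finite values")
        if len(set(self.features)) != p:
            raise ValueError("duplicate feature identifiers")

    @property
    def p(self) -> int:
        return len(self.features)

    @property
    def n1(self) -> int:
        return self.X1.shape[0]

    @property
    def n2(self) -> int:
        return self.X2.shape[0]

    def swapped(self) -> "ConditionPair":
        """Return the pair with the two condition labels exchanged."""
        return ConditionPair(self.features, self.X2, self.X1, self.standardized)


def _standardize_matrix(X: np.ndarray, features: Sequence[str], cond: str) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population convention: Gram diagonal becomes exactly N
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance feature '{features[bad[0]]}' in {cond}; "
            "remove constant columns before fitting"
        )
    return (X - mu) / sd


def standardize(pair: ConditionPair) -> ConditionPair:
    """Center and scale every column to unit population variance, per condition.

    Lasso penalties are not scale invariant, and the closed-form penalty
    formulas assume unit-variance variables, so all fitting happens on the
    standardized scale.  Idempotent to floating-point accuracy.
    """
    Z1 = _standardize_matrix(pair.X1, pair.features, "condition 1")
    Z2 = _standardize_matrix(pair.X2, pair.features, "condition 2")
    return ConditionPair(pair.features, Z1, Z2, standardized=True)


@dataclass(frozen=True)
class CoefficientPair:
    """Per-predictor coefficient duo (beta under condition 1 and 2).

    ``(0.0, 0.0)`` encodes conditional independence of the predictor and the
    response node in both conditions; exactly equal nonzero values encode a
    common (fused) edge.
    """

    predictor_index: int
    beta1: float
    beta2: float

    @property
    def is_zero(self) -> bool:
        return self.beta1 == 0.0 and self.beta2 == 0.0

    @property
    def is_fused(self) -> bool:
        return self.beta1 == self.beta2 and self.beta1 != 0.0


@dataclass(frozen=True)
class RegularizationPair:
    """Penalty pair: ``lambda1`` controls overall sparsity of both condition
    networks; ``lambda2`` penalizes cross-condition coefficient differences
    and thus controls differential-edge sparsity."""

    lambda1: float
    lambda2: float
    provenance: str = "manual"  # manual | cross_validation | fpr_control

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be nonnegative")
        if self.provenance not in ("manual", "cross_validation", "fpr_control"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class NodeRegressionProblem:
    """One node's joint two-condition sparse regression.

    ``group_weights`` are the per-group error normalization factors: in
    weighted mode ``(1/N1, 1/N2)`` so each group contributes its mean squared
    error (sample-size unbiased); in legacy mode ``(1, 1)`` so each group
    contributes its raw squared error.
    """

    node_index: int
    response1: np.ndarray
    response2: np.ndarray
    predictors1: np.ndarray
    predictors2: np.ndarray
    predictor_indices: np.ndarray
    group_weights: tuple[float, float]

    @property
    def n_predictors(self) -> int:
        return self.predictors1.shape[1]


def build_node_problem(
    pair: ConditionPair, node_index: int, weighted: bool = True
) -> NodeRegressionProblem:
    """Extract node ``node_index``'s regression: its column as response, the
    remaining ``p - 1`` columns as predictors, per condition."""
    if not pair.standardized:
        raise ValueError("standardize the pair before building node problems")
    p = pair.p
    if not (0 <= node_index < p):
        raise IndexError(f"node_index {node_index} out of range [0, {p})")
    others = np.array([j for j in range(p) if j != node_index], dtype=np.int64)
    weights = (1.0 / pair.n1, 1.0 / pair.n2) if weighted else (1.0, 1.0)
    return NodeRegressionProblem(
        node_index=node_index,
        response1=pair.X1[:, node_index].copy(),
        response2=pair.X2[:, node_index].copy(),
        predictors1=pair.X1[:, others].copy(),
        predictors2=pair.X2[:, others].copy(),
        predictor_indices=others,
        group_weights=weights,
    )
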