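"""Data-driven selection of the two penalty weights.

Two routes are provided:

* closed-form false-positive-rate (FPR) control —

      lambda1 = (2 / sqrt(N)) * PhiInv(1 - alpha1 / (2 p^2))
      lambda2 = (1/2) * tanh( (2 / sqrt(N-3)) * PhiInv(1 - alpha2/2) )
                * (1 - mean(rho1 * rho2))

  where ``N`` is the total sample count over both groups, ``alpha1`` /
  ``alpha2`` are the target FPRs of the common and the differential network,
  PhiInv is the standard-normal quantile and ``mean(rho1*rho2)`` averages the
  product of the two conditions' sample correlations over feature pairs.
  The lambda1 formula is the classical neighborhood-selection threshold with
  a per-comparison correction over the p^2 candidate coefficients; the
  lambda2 formula is a Fisher-z threshold on the cross-condition correlation
  difference, shrunk by how correlated the two conditions already are.

* combinatorial K-fold cross-validation over a (lambda1, lambda2) grid,
  scoring held-out mean squared prediction error aggregated over nodes with
  the same per-group normalization as the fitting objective.

Both formulas assume standardized (unit-variance) variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.model_selection import KFold

from .data import ConditionPair, RegularizationPair, standardize
from .solver import coefficient_matrices, lambda_max, solve_all_nodes

__all__ = [
    "FprSpec",
    "CvResult",
    "lambda1_from_fpr",
    "lambda2_from_fpr",
    "estimate_rho_product_mean",
    "select_fpr",
    "default_grid",
    "cross_validate",
]


@dataclass(frozen=True)
class FprSpec:
    """Inputs of the closed-form penalty formulas."""

    alpha1: float
    alpha2: float
    n_total: int
    p: int
    rho_product_mean: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha1 < 1 and 0 < self.alpha2 < 1):
            raise ValueError("alpha1, alpha2 must lie in (0, 1)")
        if self.n_total < 4:
            raise ValueError("need at least 4 total samples (N - 3 > 0)")
        if self.p < 2:
            raise ValueError("need p >= 2")
        if not (-1 < self.rho_product_mean < 1):
            raise ValueError("rho_product_mean must lie in (-1, 1)")


def lambda1_from_fpr(spec: FprSpec) -> float:
    """Common-network sparsity penalty controlling FPR ``alpha1``."""
    tail = spec.alpha1 / (2.0 * spec.p**2)
    if tail >= 1:
        raise ValueError("alpha1 / (2 p^2) must be below 1")
    return float(2.0 / np.sqrt(spec.n_total) * norm.ppf(1.0 - tail))


def lambda2_from_fpr(spec: FprSpec) -> float:
    """Differential-sparsity penalty controlling FPR ``alpha2``."""
    if spec.n_total <= 3:
        raise ValueError("need N > 3")
    z = 2.0 / np.sqrt(spec.n_total - 3.0) * norm.ppf(1.0 - spec.alpha2 / 2.0)
    return float(0.5 * np.tanh(z) * (1.0 - spec.rho_product_mean))


def estimate_rho_product_mean(pair: ConditionPair) -> float:
    """Mean over unordered feature pairs of the product of the two
    conditions' sample correlations — the mediating statistic of the
    lambda2 formula."""
    if pair.p < 2:
        raise ValueError("need p >= 2")
    R1 = np.corrcoef(pair.X1, rowvar=False)
    R2 = np.corrcoef(pair.X2, rowvar=False)
    iu = np.triu_indices(pair.p, k=1)
    return float(np.mean(R1[iu] * R2[iu]))


def select_fpr(
    pair: ConditionPair, alpha1: float = 0.05, alpha2: float = 0.05
) -> RegularizationPair:
    """FPR-controlled penalty pair for a dataset."""
    if not pair.standardized:
        pair = standardize(pair)
    spec = FprSpec(
        alpha1=alpha1,
        alpha2=alpha2,
        n_total=pair.n1 + pair.n2,
        p=pair.p,
        rho_product_mean=estimate_rho_product_mean(pair),
    )
    return RegularizationPair(
        lambda1_from_fpr(spec), lambda2_from_fpr(spec), provenance="fpr_control"
    )


@dataclass(frozen=True)
class CvResult:
    grid: tuple[tuple[float, float], ...]
    mean_error: np.ndarray
    selected: RegularizationPair
    n_folds: int
    seed: int


def default_grid(
    pair: ConditionPair,
    n_lambda1: int = 10,
    n_lambda2: int = 6,
    lambda1_min: float = 0.02,
) -> list[tuple[float, float]]:
    """Log-spaced lambda1 in [lambda1_min, lambda_max] crossed with linear
    lambda2 in [0, lambda1/2]."""
    lmax = max(lambda_max(pair), 2 * lambda1_min)
    l1s = np.geomspace(lambda1_min, lmax, n_lambda1)
    grid = []
    for l1 in l1s:
        for l2 in np.linspace(0.0, l1 / 2.0, n_lambda2):
            grid.append((float(l1), float(l2)))
    return grid


def _condition_folds(n: int, n_folds: int, rng: np.random.Generator):
    kf = KFold(n_splits=n_folds, shuffle=True,
               random_state=int(rng.integers(0, 2**31 - 1)))
    return list(kf.split(np.arange(n)))


def cross_validate(
    pair: ConditionPair,
    grid: list[tuple[float, float]] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    weighted: bool = True,
    tol: float = 1e-5,
    max_sweeps: int = 10_000,
) -> CvResult:
    """K-fold CV over the penalty grid.

    Folds are drawn within each condition (stratified by group).  Each
    training split is standardized on its own; held-out samples are mapped
    with the training statistics so errors live on the training scale.  The
    per-point score is the per-group mean squared prediction error, summed
    over conditions and nodes and averaged over folds.  Ties are broken
    toward the larger (lambda1, lambda2) pair, preferring the sparser model.
    """
    if n_folds not in (5, 10):
        raise ValueError("n_folds must be 5 or 10")
    if pair.n1 < n_folds or pair.n2 < n_folds:
        raise ValueError("each condition needs at least n_folds samples")
    if grid is None:
        std = pair if pair.standardized else standardize(pair)
        grid = default_grid(std)
    if len(grid) == 0:
        raise ValueError("empty penalty grid")

    rng = np.random.default_rng(seed)
    folds1 = _condition_folds(pair.n1, n_folds, rng)
    folds2 = _condition_folds(pair.n2, n_folds, rng)
    errors = np.zeros((len(grid), n_folds))

    for f, ((tr1, te1), (tr2, te2)) in enumerate(zip(folds1, folds2)):
        mu1, sd1 = pair.X1[tr1].mean(0), pair.X1[tr1].std(0)
        mu2, sd2 = pair.X2[tr2].mean(0), pair.X2[tr2].std(0)
        if np.any(sd1 == 0) or np.any(sd2 == 0):
            raise ValueError("zero-variance feature within a CV training fold")
        train = ConditionPair(
            pair.features,
            (pair.X1[tr1] - mu1) / sd1,
            (pair.X2[tr2] - mu2) / sd2,
            standardized=True,
        )
        T1 = (pair.X1[te1] - mu1) / sd1
        T2 = (pair.X2[te2] - mu2) / sd2
        w1 = 1.0 / (2 * len(te1)) if weighted else 0.5
        w2 = 1.0 / (2 * len(te2)) if weighted else 0.5
        for g, (l1, l2) in enumerate(grid):
            reg = RegularizationPair(l1, l2)
            states = solve_all_nodes(
                train, reg, strategy="corr_mtx", weighted=weighted,
                tol=tol, max_sweeps=max_sweeps, screen=True,
            )
            B1, B2 = coefficient_matrices(states, pair.p)
            R1 = T1 - T1 @ B1.T
            R2 = T2 - T2 @ B2.T
            errors[g, f] = w1 * np.sum(R1**2) + w2 * np.sum(R2**2)

    mean_error = errors.mean(axis=1)
    best = min(
        range(len(grid)),
        key=lambda g: (mean_error[g], -grid[g][0], -grid[g][1]),
    )
    selected = RegularizationPair(
        grid[best][0], grid[best][1], provenance="cross_validation"
    )
    return CvResult(tuple(grid), mean_error, selected, n_folds, seed)
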