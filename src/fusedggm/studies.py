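"""Reusable validation study designs.

Two Monte-Carlo studies mirror the method's validation protocol:

* :func:`imbalance_null_study` — both conditions share one generating
  network (the null hypothesis: every detected differential edge is false)
  and the samples are split into groups of unequal size.  The study counts
  where the false differential edges land, contrasting the mean-squared-
  error (weighted) objective with the legacy squared-error objective.

* :func:`joint_vs_separate_study` — rewired two-condition data; the jointly
  fused fit (penalties selected by cross-validation) is compared against
  independent per-condition lasso fits on differential-edge F1.

For the legacy mode both penalties are multiplied by ``N_total / 2`` so the
two objectives coincide exactly for balanced groups; any remaining contrast
under imbalance is attributable to the error weighting itself.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import RegularizationPair, standardize
from .evaluate import baseline_separate_lasso, score_network
from .hyperparams import (
    FprSpec,
    cross_validate,
    estimate_rho_product_mean,
    lambda1_from_fpr,
    lambda2_from_fpr,
)
from .network import assemble, fit_differential_network
from .simulate import SimulationSpec, simulate_study
from .solver import solve_all_nodes

__all__ = [
    "ImbalanceNullResult",
    "imbalance_null_study",
    "JointAdvantageResult",
    "joint_vs_separate_study",
]


@dataclass(frozen=True)
class ImbalanceNullResult:
    """Aggregate false-differential-edge counts under the null."""

    weighted: bool
    n_small: int
    n_large: int
    n_seeds: int
    to_small: int  # condition-specific edges present only in the small group
    to_large: int
    diff_weight: int  # both nonzero, unequal (assigned to neither group)
    common: int

    @property
    def n_condition_specific(self) -> int:
        return self.to_small + self.to_large

    @property
    def fraction_to_small(self) -> float:
        n = self.n_condition_specific
        return self.to_small / n if n else float("nan")


def imbalance_null_study(
    n_small: int = 20,
    n_large: int = 200,
    p: int = 50,
    n_seeds: int = 100,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    weighted: bool = True,
    network_type: str = "random",
    base_seed: int = 0,
) -> ImbalanceNullResult:
    """Null-hypothesis imbalance study over both group orders.

    For every seed the study is run twice — small group first (n1:n2 =
    n_small:n_large) and small group second — so any labeling asymmetry
    cancels and only the size asymmetry remains.  Penalties come from the
    closed-form FPR formulas on each simulated dataset; in legacy mode they
    are rescaled by N/2 (see module docstring).
    """
    to_small = to_large = dw = common = 0
    N = n_small + n_large
    for s in range(n_seeds):
        for small_is_1 in (True, False):
            n1, n2 = (n_small, n_large) if small_is_1 else (n_large, n_small)
            spec = SimulationSpec(
                network_type, p=p, n1=n1, n2=n2,
                rewire_fraction=0.0, seed=base_seed + s,
            )
            _, pair = simulate_study(spec)
            std = standardize(pair)
            fpr = FprSpec(alpha1, alpha2, N, p,
                          estimate_rho_product_mean(std))
            l1 = lambda1_from_fpr(fpr)
            l2 = lambda2_from_fpr(fpr)
            if not weighted:
                l1 *= N / 2
                l2 *= N / 2
            states = solve_all_nodes(
                std, RegularizationPair(l1, l2, "fpr_control"),
                weighted=weighted, screen=True,
            )
            net = assemble(states, std.features)
            small_cls = "condition1_only" if small_is_1 else "condition2_only"
            large_cls = "condition2_only" if small_is_1 else "condition1_only"
            for e in net.edges:
                if e.edge_class == small_cls:
                    to_small += 1
                elif e.edge_class == large_cls:
                    to_large += 1
                elif e.edge_class == "differential_weight":
                    dw += 1
                else:
                    common += 1
    return ImbalanceNullResult(
        weighted=weighted, n_small=n_small, n_large=n_large,
        n_seeds=n_seeds, to_small=to_small, to_large=to_large,
        diff_weight=dw, common=common,
    )


@dataclass(frozen=True)
class JointAdvantageResult:
    network_type: str
    seeds: tuple[int, ...]
    joint_f1: tuple[float, ...]
    separate_f1: tuple[float, ...]

    @property
    def wins(self) -> int:
        return sum(j >= s for j, s in zip(self.joint_f1, self.separate_f1))


def joint_vs_separate_study(
    network_type: str = "random",
    p: int = 100,
    n1: int = 100,
    n2: int = 100,
    rewire_fraction: float = 0.1,
    seeds: tuple[int, ...] = tuple(range(10)),
    cv_grid=None,
    n_folds: int = 5,
) -> JointAdvantageResult:
    """Differential-edge F1 of the fused joint fit (CV-selected penalties)
    versus independent per-condition lasso fits at the same lambda1."""
    joint_scores = []
    sep_scores = []
    for s in seeds:
        spec = SimulationSpec(
            network_type, p=p, n1=n1, n2=n2,
            rewire_fraction=rewire_fraction, seed=s,
        )
        truth, pair = simulate_study(spec)
        res = cross_validate(pair, grid=cv_grid, n_folds=n_folds, seed=s)
        std = standardize(pair)
        net = fit_differential_network(std, res.selected, screen=True)
        base = baseline_separate_lasso(std, res.selected.lambda1, screen=True)
        joint_scores.append(score_network(net, truth, "differential").f1)
        sep_scores.append(score_network(base, truth, "differential").f1)
    return JointAdvantageResult(
        network_type, tuple(seeds), tuple(joint_scores), tuple(sep_scores)
    )
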