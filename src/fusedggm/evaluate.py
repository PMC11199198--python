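"""Scoring recovered networks against simulated ground truth.

Four measures over unordered node pairs: precision, recall, F1, and the
partial ROC area at a low false-positive-rate cap (default 0.1), normalized
to [0, 1] by the cap.  Targets:

``common``
    positives are ground-truth common edges (support intersection of the two
    precision matrices); a pair counts as predicted positive when both
    condition coefficients are nonzero.
``differential``
    positives are the support symmetric difference; predicted positive means
    nonzero in exactly one condition.

A separate-lasso baseline (each condition fit independently, i.e. the
``lambda2 = 0`` path) is provided as the comparator that joint fusion is
meant to beat on differential-edge recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data import ConditionPair, RegularizationPair
from .network import DifferentialNetwork, fit_differential_network
from .simulate import GroundTruth

__all__ = [
    "EvalReport",
    "predicted_edge_sets",
    "score_network",
    "score_edge_sets",
    "edge_scores",
    "roc_curve",
    "pr_curve",
    "baseline_separate_lasso",
]

TARGETS = ("common", "differential")


@dataclass(frozen=True)
class EvalReport:
    target: str
    precision: float
    recall: float
    f1: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN over unordered pairs

    @property
    def tp(self) -> int:
        return self.confusion[0]


def predicted_edge_sets(
    net: DifferentialNetwork,
) -> dict[str, set[tuple[int, int]]]:
    """Index-pair sets: per-condition supports, common and differential."""
    sets: dict[str, set[tuple[int, int]]] = {
        "support1": set(), "support2": set(), "common": set(), "differential": set()
    }
    for (i, j), e in net.edge_index_pairs().items():
        in1 = e.beta1 != 0.0
        in2 = e.beta2 != 0.0
        if in1:
            sets["support1"].add((i, j))
        if in2:
            sets["support2"].add((i, j))
        if in1 and in2:
            sets["common"].add((i, j))
        if in1 != in2:
            sets["differential"].add((i, j))
    return sets


def score_edge_sets(
    predicted: set[tuple[int, int]] | frozenset[tuple[int, int]],
    truth: set[tuple[int, int]] | frozenset[tuple[int, int]],
    n_nodes: int,
    target: str = "differential",
) -> EvalReport:
    """Confusion counts and P/R/F1 over all p(p-1)/2 unordered pairs."""
    predicted = set(predicted)
    truth = set(truth)
    n_pairs = n_nodes * (n_nodes - 1) // 2
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = n_pairs - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvalReport(target, precision, recall, f1, (tp, fp, fn, tn))


def score_network(
    predicted: DifferentialNetwork, truth: GroundTruth, target: str
) -> EvalReport:
    """Score an assembled network against a simulation ground truth."""
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    if predicted.p != truth.p:
        raise ValueError(
            f"node mismatch: network has {predicted.p}, truth has {truth.p}"
        )
    sets = predicted_edge_sets(predicted)
    true_set = truth.common_edges if target == "common" else truth.diff_edges
    return score_edge_sets(sets[target], true_set, truth.p, target)


def edge_scores(
    net: DifferentialNetwork, target: str
) -> dict[tuple[int, int], float]:
    """Ranking score per present pair: min(|beta1|, |beta2|) for the common
    target (both conditions must carry the edge), |beta1 - beta2| for the
    differential target.  Absent pairs implicitly score 0."""
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    out = {}
    for (i, j), e in net.edge_index_pairs().items():
        if target == "common":
            s = min(abs(e.beta1), abs(e.beta2))
        else:
            s = abs(e.beta1 - e.beta2)
        if s > 0:
            out[(i, j)] = s
    return out


def roc_curve(
    score_ranked_edges: dict[tuple[int, int], float],
    truth: GroundTruth,
    target: str,
    fpr_cap: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Partial ROC over all unordered pairs.

    Returns (fpr, tpr, partial_area) with the area over FPR in
    [0, fpr_cap] normalized by the cap, so a perfect ranking scores 1.0 and
    chance scores about 0.5.
    """
    if not (0 < fpr_cap <= 1):
        raise ValueError("fpr_cap must lie in (0, 1]")
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    true_set = truth.common_edges if target == "common" else truth.diff_edges
    p = truth.p
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    y_true = np.array([pair in true_set for pair in pairs], dtype=int)
    if y_true.all() or not y_true.any():
        raise ValueError("truth labels are all-positive or all-negative")
    y_score = np.array([score_ranked_edges.get(pair, 0.0) for pair in pairs])
    fpr, tpr, _ = _sk_roc_curve(y_true, y_score, drop_intermediate=False)
    tpr_cap = float(np.interp(fpr_cap, fpr, tpr))
    mask = fpr <= fpr_cap
    fx = np.concatenate([fpr[mask], [fpr_cap]])
    fy = np.concatenate([tpr[mask], [tpr_cap]])
    area = float(np.trapezoid(fy, fx) / fpr_cap)
    return fpr, tpr, area


def pr_curve(
    score_ranked_edges: dict[tuple[int, int], float],
    truth: GroundTruth,
    target: str,
) -> list[tuple[float, float]]:
    """Precision-recall points over all unordered pairs, ranked by the same
    scores as :func:`roc_curve`; returned as (recall, precision) pairs in
    increasing recall order."""
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    true_set = truth.common_edges if target == "common" else truth.diff_edges
    p = truth.p
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    y_true = np.array([pair in true_set for pair in pairs], dtype=int)
    if not y_true.any():
        raise ValueError("truth labels contain no positives")
    y_score = np.array([score_ranked_edges.get(pair, 0.0) for pair in pairs])
    precision, recall, _ = _sk_pr_curve(y_true, y_score)
    pts = sorted(zip(recall.tolist(), precision.tolist()))
    return [(float(r), float(q)) for r, q in pts]


def baseline_separate_lasso(
    pair: ConditionPair, lambda1: float, **solver_kwargs
) -> DifferentialNetwork:
    """Two independent single-condition lasso fits (the lambda2 = 0 path of
    the joint objective); differential edges are the support symmetric
    difference."""
    reg = RegularizationPair(lambda1, 0.0, provenance="manual")
    return fit_differential_network(pair, reg, **solver_kwargs)
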