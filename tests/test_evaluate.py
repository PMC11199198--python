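"""Evaluation measures: confusion arithmetic, partial ROC, baseline."""

import numpy as np
import pytest

from fusedggm import (
    GroundTruth,
    RegularizationPair,
    baseline_separate_lasso,
    edge_scores,
    fit_differential_network,
    roc_curve,
    score_edge_sets,
    score_network,
    standardize,
)
from fusedggm.evaluate import predicted_edge_sets
from fusedggm.simulate import SimulationSpec, simulate_study


def _truth_from_edges(p, edges1, edges2):
    def om(edges):
        m = np.zeros((p, p))
        for i, j in edges:
            m[i, j] = m[j, i] = 0.4
        np.fill_diagonal(m, np.abs(m).sum(1) + 0.1 + 1.0)
        return m

    return GroundTruth(om(edges1), om(edges2))


def test_hand_built_confusion_counts():
    # truth: 3 differential edges; prediction: 2 TP + 1 FP
    truth = {(0, 1), (0, 2), (1, 2)}
    pred = {(0, 1), (0, 2), (3, 4)}
    r = score_edge_sets(pred, truth, n_nodes=5)
    assert r.confusion == (2, 1, 1, 6)
    assert r.precision == pytest.approx(2 / 3)
    assert r.recall == pytest.approx(2 / 3)
    assert r.f1 == pytest.approx(2 / 3)
    assert sum(r.confusion) == 5 * 4 // 2


def test_perfect_and_empty_predictions():
    truth = {(0, 1), (2, 3)}
    perfect = score_edge_sets(truth, truth, 6)
    assert (perfect.precision, perfect.recall, perfect.f1) == (1.0, 1.0, 1.0)
    empty = score_edge_sets(set(), truth, 6)
    assert empty.recall == 0.0 and empty.f1 == 0.0


def test_score_network_targets(small_study):
    truth, _, std = small_study
    net = fit_differential_network(std, RegularizationPair(0.2, 0.05))
    rc = score_network(net, truth, "common")
    rd = score_network(net, truth, "differential")
    sets = predicted_edge_sets(net)
    assert rc.confusion[0] == len(sets["common"] & truth.common_edges)
    assert rd.confusion[0] == len(sets["differential"] & truth.diff_edges)
    with pytest.raises(ValueError):
        score_network(net, truth, "bogus")


def test_scoring_invariant_to_node_relabeling(small_study):
    truth, _, std = small_study
    net = fit_differential_network(std, RegularizationPair(0.2, 0.05))
    r = score_network(net, truth, "differential")
    perm = np.random.default_rng(0).permutation(truth.p)
    P = np.eye(truth.p)[perm]
    truth_perm = GroundTruth(P @ truth.omega1 @ P.T, P @ truth.omega2 @ P.T)
    pred = predicted_edge_sets(net)["differential"]
    inv = np.argsort(perm)
    pred_perm = {tuple(sorted((inv[i], inv[j]))) for i, j in pred}
    r2 = score_edge_sets(pred_perm, truth_perm.diff_edges, truth.p)
    assert r2.confusion == r.confusion


def test_partial_roc_perfect_random_reversed():
    truth = _truth_from_edges(20, [(0, 1), (2, 3), (4, 5)], [(0, 1), (2, 3), (4, 5)])
    pos = truth.common_edges
    all_pairs = [(i, j) for i in range(20) for j in range(i + 1, 20)]
    perfect = {pair: (2.0 if pair in pos else 1.0) for pair in all_pairs}
    _, _, a = roc_curve(perfect, truth, "common", fpr_cap=0.1)
    assert a == pytest.approx(1.0)
    reversed_ = {pair: (1.0 if pair in pos else 2.0) for pair in all_pairs}
    _, _, a0 = roc_curve(reversed_, truth, "common", fpr_cap=0.1)
    assert a0 == pytest.approx(0.0)
    # random scores: chance level of the cap-normalized partial area is
    # fpr_cap/2 (the diagonal's area over [0, cap] divided by the cap),
    # recovering 0.5 at cap = 1
    rng = np.random.default_rng(0)
    for cap, expect in ((0.5, 0.25), (1.0, 0.5)):
        areas = [
            roc_curve({pair: rng.random() for pair in all_pairs},
                      truth, "common", fpr_cap=cap)[2]
            for _ in range(50)
        ]
        assert abs(np.mean(areas) - expect) < 0.08


def test_partial_roc_cap_one_equals_full_auc():
    truth = _truth_from_edges(15, [(0, 1), (1, 2)], [(0, 1), (1, 2)])
    rng = np.random.default_rng(1)
    scores = {
        (i, j): rng.random() for i in range(15) for j in range(i + 1, 15)
    }
    from sklearn.metrics import roc_auc_score

    pairs = sorted(scores)
    y = [int(pair in truth.common_edges) for pair in pairs]
    s = [scores[pair] for pair in pairs]
    _, _, a = roc_curve(scores, truth, "common", fpr_cap=1.0)
    assert a == pytest.approx(roc_auc_score(y, s), abs=1e-10)


def test_pr_curve_perfect_ranking_has_unit_precision():
    from fusedggm import pr_curve

    truth = _truth_from_edges(12, [(0, 1), (2, 3)], [(0, 1), (2, 3)])
    pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)]
    scores = {p: (2.0 if p in truth.common_edges else 1.0) for p in pairs}
    pts = pr_curve(scores, truth, "common")
    # at full recall the perfect ranking keeps precision 1
    assert (1.0, 1.0) in pts
    rec = [r for r, _ in pts]
    assert rec == sorted(rec)


def test_roc_rejects_degenerate_truth():
    om = np.eye(10)
    truth = GroundTruth(om, om.copy())  # no edges at all
    with pytest.raises(ValueError, match="all-"):
        roc_curve({}, truth, "common")


def test_edge_scores_conventions(small_study):
    truth, _, std = small_study
    net = fit_differential_network(std, RegularizationPair(0.2, 0.05))
    sc = edge_scores(net, "common")
    sd = edge_scores(net, "differential")
    idx = net.edge_index_pairs()
    for pair, e in idx.items():
        if min(abs(e.beta1), abs(e.beta2)) > 0:
            assert sc[pair] == min(abs(e.beta1), abs(e.beta2))
        if e.beta1 != e.beta2:
            assert sd[pair] == abs(e.beta1 - e.beta2)


def test_baseline_identical_conditions_no_differential_edges():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(60, 10))
    from fusedggm import ConditionPair

    pair = standardize(
        ConditionPair([f"g{i}" for i in range(10)], X, X.copy())
    )
    net = baseline_separate_lasso(pair, 0.2)
    assert predicted_edge_sets(net)["differential"] == set()


def test_baseline_equals_lambda2_zero_joint_fit(small_study):
    _, _, std = small_study
    base = baseline_separate_lasso(std, 0.18, tol=1e-10)
    joint = fit_differential_network(
        std, RegularizationPair(0.18, 0.0), tol=1e-10
    )
    kb = {(e.node_a, e.node_b): (e.beta1, e.beta2) for e in base.edges}
    kj = {(e.node_a, e.node_b): (e.beta1, e.beta2) for e in joint.edges}
    assert kb == kj
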