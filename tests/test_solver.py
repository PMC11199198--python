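"""BCD solver: convergence, strategies, screening, parallel determinism."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from fusedggm import (
    ConditionPair,
    RegularizationPair,
    build_node_problem,
    bcd_solve,
    lambda_max,
    precompute_corr,
    solve_all_nodes,
    solve_pair_subproblem,
    standardize,
    strong_rule_screen,
    update_residual_incremental,
)
from fusedggm.simulate import SimulationSpec, simulate_study
from fusedggm.solver import coefficient_matrices, objective_value

from _oracles import convex_program_oracle


def _problem(seed=7, p=12, n1=40, n2=50, rewire=0.2):
    spec = SimulationSpec("random", p=p, n1=n1, n2=n2,
                          rewire_fraction=rewire, seed=seed)
    truth, pair = simulate_study(spec)
    return standardize(pair)


def test_full_shrinkage_above_lambda_max(small_study):
    _, _, std = small_study
    lam = lambda_max(std) * 1.01
    states = solve_all_nodes(std, RegularizationPair(lam, 0.1))
    for st in states:
        assert np.all(st.beta1 == 0.0) and np.all(st.beta2 == 0.0)


def test_identical_conditions_give_symmetric_solution():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 8))
    pair = standardize(ConditionPair([f"g{i}" for i in range(8)], X, X.copy()))
    prob = build_node_problem(pair, 0)
    st = bcd_solve(prob, RegularizationPair(0.2, 0.0), tol=1e-10)
    assert np.max(np.abs(st.beta1 - st.beta2)) < 1e-10


def test_objective_monotone_over_sweeps(small_study):
    _, _, std = small_study
    prob = build_node_problem(std, 3)
    st = bcd_solve(prob, RegularizationPair(0.15, 0.05), strategy="naive",
                   tol=1e-8, track_objective=True)
    trace = np.array(st.objective_trace)
    assert np.all(np.diff(trace) <= 1e-12)


def test_residual_invariant_holds(small_study):
    _, _, std = small_study
    prob = build_node_problem(std, 1)
    st = bcd_solve(prob, RegularizationPair(0.2, 0.1), strategy="resi_upd")
    assert np.max(np.abs(
        st.residual1 - (prob.response1 - prob.predictors1 @ st.beta1)
    )) < 1e-8


@pytest.mark.parametrize("seed", range(6))
def test_objective_matches_convex_program(seed):
    """Full-node objective agrees with an independent QP solution."""
    std = _problem(seed=seed)
    rng = np.random.default_rng(seed)
    prob = build_node_problem(std, int(rng.integers(0, 12)))
    reg = RegularizationPair(rng.uniform(0.05, 0.4), rng.uniform(0.0, 0.2))
    st = bcd_solve(prob, reg, tol=1e-10)
    _, _, f_oracle = convex_program_oracle(prob, reg)
    scale = max(1.0, abs(f_oracle))
    assert abs(st.objective - f_oracle) <= 1e-6 * scale


def test_lambda2_zero_matches_sklearn_lasso(small_study):
    """Decoupled path equals two independent lasso fits (independent
    coordinate-descent implementation)."""
    _, _, std = small_study
    for node in (0, 5):
        prob = build_node_problem(std, node)
        st = bcd_solve(prob, RegularizationPair(0.15, 0.0), tol=1e-12)
        for X, y, beta in (
            (prob.predictors1, prob.response1, st.beta1),
            (prob.predictors2, prob.response2, st.beta2),
        ):
            skl = Lasso(alpha=0.15, fit_intercept=False, tol=1e-12,
                        max_iter=200_000).fit(X, y)
            assert np.max(np.abs(beta - skl.coef_)) < 1e-8


@pytest.mark.parametrize("seed", range(5))
def test_strategies_agree(seed):
    std = _problem(seed=seed + 20)
    prob = build_node_problem(std, seed % 12)
    reg = RegularizationPair(0.12, 0.06)
    sols = {
        s: bcd_solve(prob, reg, strategy=s, tol=1e-12)
        for s in ("naive", "resi_upd", "corr_mtx")
    }
    for s in ("resi_upd", "corr_mtx"):
        assert np.max(np.abs(sols["naive"].beta1 - sols[s].beta1)) < 1e-10
        assert np.max(np.abs(sols["naive"].beta2 - sols[s].beta2)) < 1e-10


def test_precompute_corr_reproduces_inner_products(small_study):
    _, _, std = small_study
    prob = build_node_problem(std, 2)
    t = precompute_corr(prob)
    w1, w2 = prob.group_weights
    assert np.max(np.abs(t.g1 - w1 * prob.predictors1.T @ prob.predictors1)) < 1e-12
    assert np.allclose(np.diag(t.g1), 1.0, atol=1e-10)  # standardized, weighted
    assert np.max(np.abs(t.r2 - w2 * prob.predictors2.T @ prob.response2)) < 1e-12


def test_incremental_residual_updates_do_not_drift(rng):
    n = 60
    col = rng.normal(size=n)
    y = rng.normal(size=n)
    r = y.copy()
    beta = 0.0
    betas = rng.normal(size=10_000) * 0.5
    for nb in betas:
        update_residual_incremental(r, col, beta, nb)
        beta = nb
    assert np.max(np.abs(r - (y - beta * col))) < 1e-8
    before = r.copy()
    update_residual_incremental(r, col, beta, beta)
    assert np.array_equal(before, r)  # bitwise no-op


@pytest.mark.parametrize("seed", range(8))
def test_strong_rule_screening_is_exact(seed):
    std = _problem(seed=seed + 50)
    rng = np.random.default_rng(seed)
    prob = build_node_problem(std, int(rng.integers(0, 12)))
    reg = RegularizationPair(rng.uniform(0.1, 0.5), rng.uniform(0.0, 0.2))
    plain = bcd_solve(prob, reg, tol=1e-12, screen=False)
    screened = bcd_solve(prob, reg, tol=1e-12, screen=True)
    assert np.max(np.abs(plain.beta1 - screened.beta1)) < 1e-10
    assert np.max(np.abs(plain.beta2 - screened.beta2)) < 1e-10


def test_strong_rule_inactive_at_zero_lambda(small_study):
    _, _, std = small_study
    prob = build_node_problem(std, 0)
    kept = strong_rule_screen(prob, RegularizationPair(0.0, 0.1))
    assert kept.size == prob.n_predictors


def test_strong_rule_discards_all_above_lambda_max(small_study):
    _, _, std = small_study
    prob = build_node_problem(std, 0)
    lam = lambda_max(std) * 1.05
    kept = strong_rule_screen(prob, RegularizationPair(lam, 0.0))
    assert kept.size == 0
    st = bcd_solve(prob, RegularizationPair(lam, 0.0), screen=True)
    assert np.all(st.beta1 == 0.0) and np.all(st.beta2 == 0.0)


def test_parallel_solve_is_deterministic(small_study):
    _, _, std = small_study
    reg = RegularizationPair(0.15, 0.05)
    s1 = solve_all_nodes(std, reg, n_workers=1)
    s4 = solve_all_nodes(std, reg, n_workers=4)
    B1a, B2a = coefficient_matrices(s1, std.p)
    B1b, B2b = coefficient_matrices(s4, std.p)
    assert np.max(np.abs(B1a - B1b)) < 1e-12
    assert np.max(np.abs(B2a - B2b)) < 1e-12


def test_two_node_solution_equals_pair_closed_form():
    rng = np.random.default_rng(11)
    X1 = rng.normal(size=(50, 2))
    X2 = rng.normal(size=(60, 2))
    pair = standardize(ConditionPair(["a", "b"], X1, X2))
    reg = RegularizationPair(0.1, 0.05)
    st = solve_all_nodes(pair, reg)[0]
    prob = build_node_problem(pair, 0)
    w1, w2 = prob.group_weights
    a1 = w1 * prob.predictors1[:, 0] @ prob.predictors1[:, 0]
    a2 = w2 * prob.predictors2[:, 0] @ prob.predictors2[:, 0]
    c1 = w1 * prob.predictors1[:, 0] @ prob.response1 / a1
    c2 = w2 * prob.predictors2[:, 0] @ prob.response2 / a2
    b1, b2 = solve_pair_subproblem(a1, a2, c1, c2, reg.lambda1, reg.lambda2)
    assert st.beta1[0] == pytest.approx(b1, abs=1e-10)
    assert st.beta2[0] == pytest.approx(b2, abs=1e-10)


def test_huge_fusion_penalty_fuses_every_pair(small_study):
    _, _, std = small_study
    states = solve_all_nodes(std, RegularizationPair(0.1, 1e3))
    for st in states:
        assert np.array_equal(st.beta1, st.beta2)  # bitwise fused


def test_weighted_solution_invariant_under_group_replication(small_study):
    """Replicating every condition-2 sample leaves the weighted solution
    unchanged; the legacy solution moves."""
    _, _, std = small_study
    rep = ConditionPair(
        std.features, std.X1, np.vstack([std.X2] * 3), standardized=True
    )
    reg = RegularizationPair(0.15, 0.05)
    a = solve_all_nodes(std, reg, weighted=True, tol=1e-10)
    b = solve_all_nodes(rep, reg, weighted=True, tol=1e-10)
    Ba = coefficient_matrices(a, std.p)
    Bb = coefficient_matrices(b, std.p)
    assert np.max(np.abs(Ba[0] - Bb[0])) < 1e-8
    assert np.max(np.abs(Ba[1] - Bb[1])) < 1e-8
    ua = solve_all_nodes(std, reg, weighted=False, tol=1e-10)
    ub = solve_all_nodes(rep, reg, weighted=False, tol=1e-10)
    Ua = coefficient_matrices(ua, std.p)
    Ub = coefficient_matrices(ub, std.p)
    assert np.max(np.abs(Ua[0] - Ub[0])) > 1e-4


def test_nonconvergence_reported(small_study):
    _, _, std = small_study
    prob = build_node_problem(std, 0)
    st = bcd_solve(prob, RegularizationPair(0.05, 0.01), max_sweeps=1)
    assert not st.converged and st.n_sweeps == 1
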