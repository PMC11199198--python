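"""Independent numeric oracles for the solver tests.

These deliberately avoid the package's closed-form/BCD code paths: the full
per-node objective is solved as a quadratic program via scipy trust-constr
on an exact reformulation (positive/negative coefficient splits plus
auxiliary variables for |b1 - b2| tied by linear equality constraints), and
the 2-D pair subproblem via Nelder-Mead polished over multiple starts plus a
dense grid.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from fusedggm.data import NodeRegressionProblem, RegularizationPair


def pair_objective(a1, a2, c1, c2, l1, l2, b1, b2):
    return (
        0.5 * a1 * (b1 - c1) ** 2
        + 0.5 * a2 * (b2 - c2) ** 2
        + l1 * (abs(b1) + abs(b2))
        + l2 * abs(b1 - b2)
    )


def pair_oracle(a1, a2, c1, c2, l1, l2):
    """Near-optimal solution of the 2-D subproblem by multi-start
    Nelder-Mead seeded from a coarse grid."""
    span = max(abs(c1), abs(c2), 1.0) * 1.5
    grid = np.linspace(-span, span, 81)
    B1, B2 = np.meshgrid(grid, grid)
    vals = pair_objective(a1, a2, c1, c2, l1, l2, B1, B2)
    k = np.argmin(vals)
    starts = [
        (B1.flat[k], B2.flat[k]),
        (c1, c2),
        (0.0, 0.0),
        ((c1 + c2) / 2, (c1 + c2) / 2),
    ]
    best, fbest = None, np.inf
    for x0 in starts:
        res = minimize(
            lambda x: pair_objective(a1, a2, c1, c2, l1, l2, x[0], x[1]),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20_000},
        )
        if res.fun < fbest:
            fbest, best = res.fun, res.x
    return best[0], best[1], fbest


def full_objective(problem: NodeRegressionProblem, reg: RegularizationPair, b1, b2):
    w1, w2 = problem.group_weights
    r1 = problem.response1 - problem.predictors1 @ b1
    r2 = problem.response2 - problem.predictors2 @ b2
    return (
        0.5 * w1 * (r1 @ r1)
        + 0.5 * w2 * (r2 @ r2)
        + reg.lambda1 * (np.abs(b1).sum() + np.abs(b2).sum())
        + reg.lambda2 * np.abs(b1 - b2).sum()
    )


def convex_program_oracle(problem: NodeRegressionProblem, reg: RegularizationPair):
    """Solve the full node objective as a QP with trust-constr.

    Variables z = [b1p, b1m, b2p, b2m, up, um] (each length m, all >= 0)
    with b_k = bkp - bkm and the equality (b1 - b2) = up - um; the penalty
    is linear in z and tight at the optimum.
    Returns (beta1, beta2, objective).
    """
    m = problem.n_predictors
    w1, w2 = problem.group_weights
    P1, P2 = problem.predictors1, problem.predictors2
    y1, y2 = problem.response1, problem.response2
    l1, l2 = reg.lambda1, reg.lambda2

    def split(z):
        b1 = z[0:m] - z[m : 2 * m]
        b2 = z[2 * m : 3 * m] - z[3 * m : 4 * m]
        u = z[4 * m : 5 * m] + z[5 * m : 6 * m]
        return b1, b2, u

    def fun(z):
        b1, b2, u = split(z)
        r1 = y1 - P1 @ b1
        r2 = y2 - P2 @ b2
        return (
            0.5 * w1 * (r1 @ r1)
            + 0.5 * w2 * (r2 @ r2)
            + l1 * (z[0 : 4 * m].sum())
            + l2 * u.sum()
        )

    def grad(z):
        b1, b2, _ = split(z)
        g1 = -w1 * (P1.T @ (y1 - P1 @ b1))
        g2 = -w2 * (P2.T @ (y2 - P2 @ b2))
        g = np.empty(6 * m)
        g[0:m] = g1 + l1
        g[m : 2 * m] = -g1 + l1
        g[2 * m : 3 * m] = g2 + l1
        g[3 * m : 4 * m] = -g2 + l1
        g[4 * m : 5 * m] = l2
        g[5 * m : 6 * m] = l2
        return g

    H1 = w1 * (P1.T @ P1)
    H2 = w2 * (P2.T @ P2)
    H = np.zeros((6 * m, 6 * m))
    H[0 : 2 * m, 0 : 2 * m] = np.block([[H1, -H1], [-H1, H1]])
    H[2 * m : 4 * m, 2 * m : 4 * m] = np.block([[H2, -H2], [-H2, H2]])

    # (b1p - b1m) - (b2p - b2m) - (up - um) = 0
    A = np.zeros((m, 6 * m))
    I = np.eye(m)
    A[:, 0:m] = I
    A[:, m : 2 * m] = -I
    A[:, 2 * m : 3 * m] = -I
    A[:, 3 * m : 4 * m] = I
    A[:, 4 * m : 5 * m] = -I
    A[:, 5 * m : 6 * m] = I

    res = minimize(
        fun,
        np.zeros(6 * m),
        jac=grad,
        hess=lambda z: H,
        method="trust-constr",
        constraints=[LinearConstraint(A, 0.0, 0.0)],
        bounds=[(0.0, None)] * (6 * m),
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000},
    )
    # active-set polish: SLSQP warm-started at the interior-point solution
    res2 = minimize(
        fun,
        res.x,
        jac=grad,
        method="SLSQP",
        constraints=[{"type": "eq", "fun": lambda z: A @ z, "jac": lambda z: A}],
        bounds=[(0.0, None)] * (6 * m),
        options={"ftol": 1e-16, "maxiter": 500},
    )
    z = res2.x if res2.fun < res.fun else res.x
    b1, b2, _ = split(z)
    return b1, b2, full_objective(problem, reg, b1, b2)
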