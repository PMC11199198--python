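"""Compiled inner loops for the block-coordinate-descent solver.

The per-block subproblem (one predictor, coefficients for both conditions)
is a 2-D convex problem

    f(b1, b2) = a1/2 (b1-c1)^2 + a2/2 (b2-c2)^2
                + lam1 (|b1| + |b2|) + lam2 |b1 - b2|

whose global minimizer is found exactly by enumerating the stationary points
of every smooth region together with the minimizers restricted to the three
kink lines b1 = 0, b2 = 0, b1 = b2.  Zero and fused solutions are produced
as exact floating-point zeros / bitwise-equal pairs, which is what makes
edge classification downstream tolerance-free.
"""

import numpy as np
from numba import njit

__all__ = ["pair_minimize", "bcd_gram"]


@njit(cache=True, nogil=True)
def _soft(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True, nogil=True)
def _pair_obj(a1, a2, c1, c2, l1, l2, b1, b2):
    return (
        0.5 * a1 * (b1 - c1) ** 2
        + 0.5 * a2 * (b2 - c2) ** 2
        + l1 * (abs(b1) + abs(b2))
        + l2 * abs(b1 - b2)
    )


@njit(cache=True, nogil=True)
def pair_minimize(a1, a2, c1, c2, l1, l2):
    """Exact global minimizer of the 2-D fused-pair subproblem."""
    best1 = 0.0
    best2 = 0.0
    fbest = _pair_obj(a1, a2, c1, c2, l1, l2, 0.0, 0.0)

    # fused line b1 = b2 = t: quadratic + 2*l1*|t|
    t = _soft(a1 * c1 + a2 * c2, 2.0 * l1) / (a1 + a2)
    f = _pair_obj(a1, a2, c1, c2, l1, l2, t, t)
    if f < fbest:
        fbest = f
        best1 = t
        best2 = t

    # line b1 = 0: penalty collapses to (l1 + l2)|b2|
    b2 = _soft(a2 * c2, l1 + l2) / a2
    f = _pair_obj(a1, a2, c1, c2, l1, l2, 0.0, b2)
    if f < fbest:
        fbest = f
        best1 = 0.0
        best2 = b2

    # line b2 = 0
    b1 = _soft(a1 * c1, l1 + l2) / a1
    f = _pair_obj(a1, a2, c1, c2, l1, l2, b1, 0.0)
    if f < fbest:
        fbest = f
        best1 = b1
        best2 = 0.0

    # interior of each sign region: s1 = sign b1, s2 = sign b2, d = sign(b1-b2)
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            for d in (-1.0, 1.0):
                b1 = c1 - (l1 * s1 + l2 * d) / a1
                b2 = c2 - (l1 * s2 - l2 * d) / a2
                if b1 * s1 > 0.0 and b2 * s2 > 0.0 and (b1 - b2) * d > 0.0:
                    f = _pair_obj(a1, a2, c1, c2, l1, l2, b1, b2)
                    if f < fbest:
                        fbest = f
                        best1 = b1
                        best2 = b2
    return best1, best2


@njit(cache=True, nogil=True)
def bcd_gram(G1, G2, r1, r2, l1, l2, b1, b2, active, tol, max_sweeps):
    """Cyclic BCD over the predictor pairs in ``active``, in Gram form.

    G_k = w_k * X_k' X_k (weighted predictor Gram), r_k = w_k * X_k' y_k.
    b1/b2 are updated in place.  Returns (sweeps_done, converged).
    Maintains q_k = G_k @ b_k incrementally on the active entries only.
    """
    m = active.shape[0]
    n_all = b1.shape[0]
    q1 = G1 @ b1
    q2 = G2 @ b2
    for sweep in range(max_sweeps):
        delta = 0.0
        for idx in range(m):
            j = active[idx]
            a1 = G1[j, j]
            a2 = G2[j, j]
            c1 = (r1[j] - q1[j]) / a1 + b1[j]
            c2 = (r2[j] - q2[j]) / a2 + b2[j]
            nb1, nb2 = pair_minimize(a1, a2, c1, c2, l1, l2)
            d1 = nb1 - b1[j]
            d2 = nb2 - b2[j]
            if d1 != 0.0:
                for t in range(m):
                    i2 = active[t]
                    q1[i2] += G1[i2, j] * d1
                b1[j] = nb1
            if d2 != 0.0:
                for t in range(m):
                    i2 = active[t]
                    q2[i2] += G2[i2, j] * d2
                b2[j] = nb2
            ad = abs(d1)
            if abs(d2) > ad:
                ad = abs(d2)
            if ad > delta:
                delta = ad
        if delta < tol:
            return sweep + 1, True
    return max_sweeps, False
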