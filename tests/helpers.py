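"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the QP oracle is
generic off-the-shelf convex programming (scipy SLSQP) on the explicit
split-variable program, and the Fisher oracle enumerates the
hypergeometric distribution with factorial-based exact rationals.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def slsqp_fused_lasso(X, y, s1, s2, pairs, pair_weights, orthogonal_to=()):
    """Solve the fused-lasso least-squares problem with scipy SLSQP.

    Returns (objective, beta, bias).  Uses the same variable-splitting
    linearization, but an entirely different solver.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    pairs = np.asarray(pairs, int).reshape(-1, 2)
    m = len(pairs)
    nv = p + 1 + p + m

    def objective(z):
        r = y - X @ z[:p] - z[p]
        return r @ r

    rows = 2 * p + 2 * m + 2
    A = np.zeros((rows, nv))
    ub = np.zeros(rows)
    row = 0
    for j in range(p):
        A[row, j], A[row, p + 1 + j] = 1, -1
        row += 1
        A[row, j], A[row, p + 1 + j] = -1, -1
        row += 1
    for k, (jl, jr) in enumerate(pairs):
        A[row, jr], A[row, jl], A[row, p + 1 + p + k] = 1, -1, -1
        row += 1
        A[row, jr], A[row, jl], A[row, p + 1 + p + k] = -1, 1, -1
        row += 1
    A[row, p + 1 : 2 * p + 1] = 1
    ub[row] = s1
    row += 1
    if m:
        A[row, 2 * p + 1 :] = np.asarray(pair_weights, float)
        ub[row] = s2
    else:
        A = A[:row]
        ub = ub[:row]
    constraints = [LinearConstraint(A, -np.inf, ub)]
    if len(orthogonal_to):
        Ae = np.zeros((len(orthogonal_to), nv))
        for i, v in enumerate(orthogonal_to):
            Ae[i, :p] = v
        constraints.append(LinearConstraint(Ae, 0.0, 0.0))
    res = minimize(
        objective,
        np.zeros(nv),
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    assert res.success, res.message
    return objective(res.x), res.x[:p], res.x[p]


def fisher_enrichment_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided enrichment p by full enumeration of tables with the margins.

    Probability of each table from the factorial form of the
    hypergeometric pmf, summed over co-membership counts >= a, all in
    exact rational arithmetic.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k: int) -> Fraction:
        kb = row1 - k
        kc = col1 - k
        kd = n - row1 - kc
        if min(kb, kc, kd) < 0:
            return Fraction(0)
        return Fraction(
            factorial(row1) * factorial(n - row1) * factorial(col1) * factorial(n - col1),
            factorial(n) * factorial(k) * factorial(kb) * factorial(kc) * factorial(kd),
        )

    total = sum((pmf(k) for k in range(a, min(row1, col1) + 1)), Fraction(0))
    return float(min(total, Fraction(1)))


def chain_pairs(p: int, boundary: int | None = None) -> np.ndarray:
    """Consecutive (j-1, j) pairs over p probes, optionally skipping one boundary."""
    pairs = [(j - 1, j) for j in range(1, p) if boundary is None or j != boundary]
    return np.asarray(pairs, int).reshape(-1, 2)
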