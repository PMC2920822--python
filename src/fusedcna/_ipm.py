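"""Dense primal-dual interior-point solver for convex quadratic programs.

Solves

    minimize    0.5 x' P x + q' x
    subject to  G x <= h
                A x  = b

with P symmetric positive semidefinite, using a Mehrotra
predictor-corrector scheme with an infeasible start and static KKT
regularization.  The inequality system may be given sparse; the reduced
KKT matrix is assembled dense and factorized with LAPACK, which is the
right regime for the few-hundred-variable problems produced by the
fused-lasso formulation (one variable block per probe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = ["IPMResult", "QPSolveError", "solve_qp_dense"]

# Static diagonal regularization of the KKT system; keeps the
# factorization well-posed when P is rank-deficient (n_samples < n_probes).
_KKT_REG = 1e-9
_STEP_FRAC = 0.99


class QPSolveError(RuntimeError):
    """Raised when the interior-point iteration fails to converge.

    Carries a ``diagnostics`` dict (status, iterations, residual norms,
    duality gap) so callers can report actionable failure information.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class IPMResult:
    x: np.ndarray
    z: np.ndarray          # multipliers of the inequalities
    s: np.ndarray          # slacks of the inequalities
    y: np.ndarray          # multipliers of the equalities
    objective: float
    iterations: int
    gap: float
    primal_residual: float
    dual_residual: float
    status: str = "optimal"
    info: dict = field(default_factory=dict)


def _max_step(v: np.ndarray, dv: np.ndarray) -> float:
    """Largest alpha in (0, 1] with v + alpha*dv >= 0 (v > 0)."""
    neg = dv < 0
    if not np.any(neg):
        return 1.0
    return float(min(1.0, np.min(-v[neg] / dv[neg])))


def solve_qp_dense(
    P: np.ndarray,
    q: np.ndarray,
    G,
    h: np.ndarray,
    A: np.ndarray | None = None,
    b: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> IPMResult:
    """Solve the QP; raise :class:`QPSolveError` on non-convergence.

    Parameters
    ----------
    P, q : quadratic and linear objective terms (P symmetric PSD).
    G, h : inequality system ``G x <= h``; ``G`` may be scipy-sparse.
    A, b : optional equality system ``A x = b``.
    tol : relative tolerance on residuals and on the mean complementarity
        gap.  1e-9 leaves comfortable headroom under the 1e-6 feasibility
        checks applied downstream.
    """
    q = np.asarray(q, dtype=float)
    h = np.asarray(h, dtype=float)
    n = q.size
    m = h.size
    sparse_G = sp.issparse(G)
    if sparse_G:
        G = G.tocsr()
    else:
        G = np.asarray(G, dtype=float)
    has_eq = A is not None and A.shape[0] > 0
    if has_eq:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        b = np.asarray(b, dtype=float)
        me = A.shape[0]
    else:
        me = 0

    if m == 0:
        # Pure equality-constrained QP: solve the KKT system directly.
        K = np.zeros((n + me, n + me))
        K[:n, :n] = P + _KKT_REG * np.eye(n)
        rhs = np.concatenate([-q, b]) if has_eq else -q
        if has_eq:
            K[:n, n:] = A.T
            K[n:, :n] = A
            K[n:, n:] = -_KKT_REG * np.eye(me)
        sol = sla.solve(K, rhs, assume_a="sym")
        x = sol[:n]
        y = sol[n:] if has_eq else np.empty(0)
        obj = 0.5 * x @ P @ x + q @ x
        return IPMResult(x, np.empty(0), np.empty(0), y, obj, 0, 0.0, 0.0, 0.0)

    x = np.zeros(n)
    y = np.zeros(me)
    # Start the slacks at the actual slack of x = 0 (clipped away from the
    # boundary) so that widely different constraint scales do not produce a
    # hugely infeasible first iterate.
    s = np.maximum(1.0, h - G @ x)
    z = np.ones(m)

    scale_d = 1.0 + max(np.max(np.abs(q)), 1.0)
    scale_p = 1.0 + np.max(np.abs(h))
    GT = G.T

    status = "max_iter"
    it = 0
    rd_n = rp_n = mu = np.inf
    for it in range(1, max_iter + 1):
        Gx = G @ x
        rx = P @ x + q + GT @ z + (A.T @ y if has_eq else 0.0)
        rz = Gx + s - h
        ry = (A @ x - b) if has_eq else np.empty(0)
        mu = float(s @ z) / m

        rd_n = float(np.max(np.abs(rx))) / scale_d
        rp_n = float(np.max(np.abs(rz))) / scale_p
        re_n = float(np.max(np.abs(ry))) / scale_p if has_eq else 0.0
        if rd_n <= tol and rp_n <= tol and re_n <= tol and mu <= tol * 10:
            status = "optimal"
            break

        w = z / s
        if sparse_G:
            GWG = (GT @ sp.diags(w) @ G).toarray()
        else:
            GWG = GT @ (w[:, None] * G)
        K = np.zeros((n + me, n + me))
        K[:n, :n] = P + GWG
        K[:n, :n] += _KKT_REG * np.eye(n)
        if has_eq:
            K[:n, n:] = A.T
            K[n:, :n] = A
            K[n:, n:] = -_KKT_REG * np.eye(me)
        try:
            lu, piv = sla.lu_factor(K)
        except sla.LinAlgError as exc:  # pragma: no cover - defensive
            raise QPSolveError(
                "KKT factorization failed", {"iteration": it}
            ) from exc

        def newton(rs: np.ndarray):
            rhs_x = -(rx + GT @ ((z * rz - rs) / s))
            rhs = np.concatenate([rhs_x, -ry]) if has_eq else rhs_x
            sol = sla.lu_solve((lu, piv), rhs)
            dx = sol[:n]
            dy = sol[n:]
            ds = -rz - G @ dx
            dz = -(rs + z * ds) / s
            return dx, dy, ds, dz

        # Predictor (affine scaling) direction.
        rs_aff = s * z
        dx, dy, ds, dz = newton(rs_aff)
        alpha_p = _max_step(s, ds)
        alpha_d = _max_step(z, dz)
        mu_aff = float((s + alpha_p * ds) @ (z + alpha_d * dz)) / m
        sigma = (max(mu_aff, 0.0) / mu) ** 3 if mu > 0 else 0.0

        # Corrector with Mehrotra's second-order term.
        rs_cor = s * z + ds * dz - sigma * mu
        dx, dy, ds, dz = newton(rs_cor)
        alpha = _STEP_FRAC * min(_max_step(s, ds), _max_step(z, dz))

        x = x + alpha * dx
        y = y + alpha * dy
        s = s + alpha * ds
        z = z + alpha * dz

    diagnostics = {
        "status": status,
        "iterations": it,
        "gap": mu,
        "dual_residual": rd_n,
        "primal_residual": rp_n,
    }
    if status != "optimal":
        # Accept a mildly looser solution before declaring failure: the
        # downstream feasibility contract is 1e-6.
        if rd_n <= 1e-7 and rp_n <= 1e-7 and mu <= 1e-7:
            status = "inaccurate"
        else:
            raise QPSolveError("interior-point solver did not converge", diagnostics)

    obj = float(0.5 * x @ P @ x + q @ x)
    return IPMResult(
        x=x, z=z, s=s, y=y, objective=obj, iterations=it, gap=mu,
        primal_residual=rp_n, dual_residual=rd_n, status=status,
        info=diagnostics,
    )
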