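"""Fused-lasso constrained least squares over aCGH probes.

The core estimator of the package: given profiles ``X`` (samples x
probes) and targets ``y`` (cluster labels in {-1, +1} treated as
regression targets), find the weight vector ``beta`` and bias ``b``
minimizing

    sum_i (y_i - beta . x_i - b)^2

subject to a sparsity budget ``sum_j |beta_j| <= s1``, a
distance-weighted piecewise-constantness budget
``sum_(j-1,j) w_{j,j-1} |beta_j - beta_{j-1}| <= s2`` over adjacent
probes on the same chromosomal arm, and optional orthogonality to
previously learned weight vectors.  Absolute values are linearized by
variable splitting, turning the problem into a convex QP solved by the
interior-point method in :mod:`fusedcna._ipm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from ._ipm import QPSolveError, solve_qp_dense
from .data import AnnotationError, ProbeMap

__all__ = [
    "FusedLassoParams",
    "FusionWeights",
    "QPSolveError",
    "QPSpec",
    "Separator",
    "compute_fusion_weights",
    "qp_objective",
    "solve_qp",
]


@dataclass(frozen=True)
class FusedLassoParams:
    """Budgets and iteration controls of the fused-lasso clustering step.

    ``s1`` is the sparseness budget (L1 norm of the weights), ``s2`` the
    piecewise-constantness budget (distance-weighted L1 norm of adjacent
    weight differences).  Both are constraint values, not penalties.
    Defaults are sized for profiles on a log2-ratio scale with events of
    amplitude near 1: a weight block of total mass ~2 over an event's
    probes is what is needed to map carriers to -1/+1 targets.
    """

    s1: float = 2.0
    s2: float = 1.0
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("budgets s1 and s2 must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass(frozen=True)
class FusionWeights:
    """Adjacent same-arm probe pairs and their fusion weights in (0, 1]."""

    pairs: np.ndarray   # (m, 2) int array of (j-1, j) probe indices
    weights: np.ndarray  # (m,) floats in (0, 1]

    def __post_init__(self):
        object.__setattr__(self, "pairs", np.asarray(self.pairs, dtype=int).reshape(-1, 2))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if len(self.pairs) != len(self.weights):
            raise ValueError("pairs and weights must have equal length")
        if len(self.weights) and (
            np.any(self.weights <= 0) or np.any(self.weights > 1)
        ):
            raise ValueError("fusion weights must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.weights)


def compute_fusion_weights(
    probe_map: ProbeMap,
    form: str | Callable[[np.ndarray], np.ndarray] = "inverse_median",
    scale: float | None = None,
) -> FusionWeights:
    """Distance-normalized fusion weights for adjacent same-arm probes.

    One (pair, weight) is emitted per pair of consecutive probes on the
    same chromosomal arm; pairs never span an arm or chromosome
    boundary.  The default ``inverse_median`` form is
    ``w = min(1, d_ref / d)`` with ``d`` the genomic gap and ``d_ref``
    the median gap over all emitted pairs (overridable via ``scale``):
    weight 1 up to the reference gap, decaying inversely beyond it, so
    that weakly spaced probes are fused less strongly.  ``uniform``
    gives weight 1 everywhere; a callable receives the gap array and
    must return weights in (0, 1].
    """
    pairs = []
    gaps = []
    for _, _, start, stop in probe_map.arm_segments():
        for j in range(start + 1, stop):
            pairs.append((j - 1, j))
            gaps.append(probe_map.position[j] - probe_map.position[j - 1])
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    gaps = np.asarray(gaps, dtype=float)
    if len(gaps) and np.any(gaps <= 0):
        raise AnnotationError("nonpositive genomic gap between adjacent probes")
    if len(gaps) == 0:
        return FusionWeights(pairs, gaps)
    if callable(form):
        weights = np.asarray(form(gaps), dtype=float)
    elif form == "uniform":
        weights = np.ones_like(gaps)
    elif form == "inverse_median":
        d_ref = float(np.median(gaps)) if scale is None else float(scale)
        weights = np.minimum(1.0, d_ref / gaps)
    else:
        raise ValueError(f"unknown fusion weight form {form!r}")
    return FusionWeights(pairs, weights)


@dataclass
class Separator:
    """Learned linear classifier: weights over probes, bias, labels.

    ``labels`` is ``None`` straight out of the QP and is filled by the
    clustering loop; when set, ``labels[i] = sign(beta . x_i + bias)``
    with ties assigned +1.
    """

    beta: np.ndarray
    bias: float
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.bias = float(self.bias)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.bias

    def assign_labels(self, X: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1}; a decision value of exactly 0 maps to +1."""
        return np.where(self.decision_values(X) >= 0.0, 1, -1)


@dataclass
class QPSpec:
    """One fused-lasso least-squares problem instance."""

    X: np.ndarray
    y: np.ndarray
    weights: FusionWeights
    params: FusedLassoParams
    orthogonal_to: Sequence[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        p = self.X.shape[1]
        for v in self.orthogonal_to:
            if np.asarray(v).shape != (p,):
                raise ValueError("orthogonality vectors must have length p")
        if len(self.weights) and int(self.weights.pairs.max()) >= p:
            raise ValueError("fusion pair index exceeds probe count")


def qp_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, bias: float) -> float:
    """Sum of squared residuals of the linear model."""
    r = np.asarray(y, float) - np.asarray(X, float) @ np.asarray(beta, float) - bias
    return float(r @ r)


def _quadratic_terms(X, y, nvar):
    n, p = X.shape
    P = np.zeros((nvar, nvar))
    P[:p, :p] = 2.0 * (X.T @ X)
    col = 2.0 * X.sum(axis=0)
    P[:p, p] = col
    P[p, :p] = col
    P[p, p] = 2.0 * n
    q = np.zeros(nvar)
    q[:p] = -2.0 * (X.T @ y)
    q[p] = -2.0 * y.sum()
    return P, q, float(y @ y)


def _solve_split_qp(X, y, s1, s2, pairs, pair_weights, orth, l1_weights=None):
    """Assemble and solve the split-variable QP.

    Variable layout: ``[beta (p), bias, t (p), r (m)]`` with ``t >= |beta|``
    elementwise and ``r >= |beta_j - beta_{j-1}|`` per fusion pair.
    """
    n, p = X.shape
    m = len(pairs)
    nvar = p + 1 + p + m
    P, q, const = _quadratic_terms(X, y, nvar)

    rows, cols, vals, h = [], [], [], []

    def add_row(entries, rhs):
        i = len(h)
        for j, v in entries:
            rows.append(i)
            cols.append(j)
            vals.append(v)
        h.append(rhs)

    t0 = p + 1
    r0 = t0 + p
    for j in range(p):
        add_row([(j, 1.0), (t0 + j, -1.0)], 0.0)
        add_row([(j, -1.0), (t0 + j, -1.0)], 0.0)
    a = np.ones(p) if l1_weights is None else np.asarray(l1_weights, float)
    add_row([(t0 + j, a[j]) for j in range(p)], float(s1))
    for k, (jl, jr) in enumerate(pairs):
        add_row([(int(jr), 1.0), (int(jl), -1.0), (r0 + k, -1.0)], 0.0)
        add_row([(int(jr), -1.0), (int(jl), 1.0), (r0 + k, -1.0)], 0.0)
    if m:
        add_row([(r0 + k, float(pair_weights[k])) for k in range(m)], float(s2))

    G = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(h), nvar)
    )
    h = np.asarray(h, dtype=float)

    A = b = None
    if len(orth):
        A = np.zeros((len(orth), nvar))
        for i, v in enumerate(orth):
            A[i, :p] = v
        b = np.zeros(len(orth))

    result = solve_qp_dense(P, q, G, h, A=A, b=b)
    beta = result.x[:p]
    bias = float(result.x[p])
    return beta, bias, result.objective + const


def _arm_components(p: int, pairs: np.ndarray) -> list[np.ndarray]:
    """Connected components of the probe chain graph (arms, plus singletons)."""
    linked_next = np.zeros(p, dtype=bool)
    for jl, jr in pairs:
        linked_next[jl] = True  # pairs are (j-1, j) over consecutive indices
    comps = []
    start = 0
    for j in range(p):
        if not linked_next[j]:
            comps.append(np.arange(start, j + 1))
            start = j + 1
    return comps


def solve_qp(spec: QPSpec) -> Separator:
    """Solve the fused-lasso QP; returns a :class:`Separator` (labels unset).

    The solution satisfies both budget constraints and every
    orthogonality constraint within 1e-6.  Degenerate budgets are
    handled exactly: ``s1 = 0`` forces ``beta = 0`` with the intercept
    at the target mean; ``s2 = 0`` forces ``beta`` constant along every
    chain of fused probes and is solved on the arm-collapsed problem.
    """
    X, y = spec.X, spec.y
    n, p = X.shape
    params = spec.params
    orth = [np.asarray(v, float) for v in spec.orthogonal_to]
    if orth:
        stacked = np.vstack(orth)
        if np.linalg.matrix_rank(stacked) >= p:
            raise np.linalg.LinAlgError(
                "orthogonality constraints span the full probe space; "
                "no non-trivial separator exists"
            )

    if params.s1 == 0.0:
        return Separator(np.zeros(p), float(np.mean(y)))

    if params.s2 == 0.0 and len(spec.weights):
        comps = _arm_components(p, spec.weights.pairs)
        Xc = np.column_stack([X[:, comp].sum(axis=1) for comp in comps])
        sizes = np.array([len(comp) for comp in comps], dtype=float)
        orth_c = [
            np.array([float(v[comp].sum()) for comp in comps]) for v in orth
        ]
        orth_c = [v for v in orth_c if np.any(v != 0.0)]
        beta_c, bias, _ = _solve_split_qp(
            Xc, y, params.s1, 0.0, np.empty((0, 2), int), np.empty(0), orth_c,
            l1_weights=sizes,
        )
        beta = np.zeros(p)
        for c, comp in zip(beta_c, comps):
            beta[comp] = c
        return Separator(beta, bias)

    beta, bias, _ = _solve_split_qp(
        X, y, params.s1, params.s2, spec.weights.pairs, spec.weights.weights, orth
    )
    return Separator(beta, bias)
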