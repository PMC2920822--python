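"""Maximum-margin clustering by alternating fused-lasso regression.

Labels are initialized with 2-means on the raw profiles, then the loop
alternates between (a) solving the fused-lasso QP with the current
{-1, +1} labels as regression targets and (b) reassigning each sample
the sign of its decision value.  The loop stops at a label fixed point,
on a label cycle (the lowest-objective state of the cycle is kept), or
after ``max_iter`` sweeps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .data import ProfileMatrix
from .qp import FusedLassoParams, FusionWeights, QPSpec, Separator, qp_objective, solve_qp

__all__ = ["MMCResult", "mmc_partition"]


@dataclass
class MMCResult:
    """Outcome of one maximum-margin clustering run.

    ``trivial`` flags the degenerate solution with every sample on one
    side of the hyperplane; ``label_history_hash`` digests the visited
    label sequence for reproducibility checks and cycle diagnostics.
    """

    separator: Separator
    n_iterations: int
    converged: bool
    trivial: bool
    label_history_hash: str
    objective: float


def _as_values(X) -> np.ndarray:
    if isinstance(X, ProfileMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _initial_labels(values: np.ndarray, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assignment = km.fit_predict(values)
    # Deterministic sign convention: the first sample's cluster is +1.
    return np.where(assignment == assignment[0], 1, -1)


def mmc_partition(
    X,
    params: FusedLassoParams,
    weights: FusionWeights,
    orthogonal_to=(),
) -> MMCResult:
    """Cluster the samples of ``X`` into two groups with a linear separator.

    Parameters
    ----------
    X : ProfileMatrix or array
        Profiles of the sample subset to split; at least two samples.
    params : FusedLassoParams
        Budgets, iteration cap and seed (seeds the 2-means start).
    weights : FusionWeights
        Adjacent-probe fusion structure of the probe map.
    orthogonal_to : sequence of arrays
        Weight vectors of previously learned separators; the new weight
        vector is constrained to be orthogonal to each.
    """
    values = _as_values(X)
    if values.shape[0] < 2:
        raise ValueError("maximum-margin clustering needs at least 2 samples")

    labels = _initial_labels(values, params.seed)
    history: dict[bytes, int] = {}
    states: list[tuple[np.ndarray, Separator, float]] = []
    digest = hashlib.blake2b(digest_size=16)

    converged = False
    final_index = -1
    for iteration in range(params.max_iter):
        key = labels.astype(np.int8).tobytes()
        digest.update(key)
        if key in history:
            cycle = states[history[key]:]
            if len(cycle) == 1:
                converged = True
                final_index = history[key]
            else:
                # Alternation entered a cycle; keep its best state.
                objectives = [obj for _, _, obj in cycle]
                final_index = history[key] + int(np.argmin(objectives))
            break
        sep = solve_qp(
            QPSpec(values, labels.astype(float), weights, params, list(orthogonal_to))
        )
        objective = qp_objective(values, labels.astype(float), sep.beta, sep.bias)
        history[key] = len(states)
        states.append((labels, sep, objective))
        labels = sep.assign_labels(values)
    else:
        final_index = len(states) - 1

    labels_final, sep, objective = states[final_index]
    sep.labels = sep.assign_labels(values)
    if converged:
        # At a fixed point the stored labels equal their own update.
        assert np.array_equal(sep.labels, labels_final)
    trivial = bool(np.all(sep.labels == sep.labels[0]))
    return MMCResult(
        separator=sep,
        n_iterations=len(states),
        converged=converged,
        trivial=trivial,
        label_history_hash=digest.hexdigest(),
        objective=objective,
    )
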