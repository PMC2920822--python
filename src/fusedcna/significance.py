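"""Permutation significance of a learned split.

The observed statistic is the Euclidean distance between the median
profiles (centroids) of the two groups defined by a frozen separator.
The null model shuffles the probes of the data set and re-applies the
same separator, producing the centroid distance of two random sample
groups; a normal distribution is fitted to the null distances and the
p-value is the upper tail at the observed distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import ProfileMatrix
from .qp import Separator

__all__ = ["EmptyGroupError", "SignificanceResult", "centroid", "split_significance"]


class EmptyGroupError(ValueError):
    """Centroid requested for an empty sample group."""


@dataclass
class SignificanceResult:
    observed_distance: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    degenerate: bool = False


def centroid(X, member_flags) -> np.ndarray:
    """Per-probe median profile of the flagged samples."""
    values = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, float)
    mask = np.asarray(member_flags, dtype=bool)
    if mask.sum() == 0:
        raise EmptyGroupError("cannot form the centroid of an empty group")
    return np.median(values[mask], axis=0)


def _shuffled(values: np.ndarray, rng: np.random.Generator, scheme: str) -> np.ndarray:
    n, p = values.shape
    if scheme == "across_samples":
        # Shuffle each probe independently across samples: sample identity
        # is destroyed, per-probe marginals are preserved, and the frozen
        # separator then carves out genuinely random sample groups.
        idx = np.argsort(rng.random((n, p)), axis=0)
        return np.take_along_axis(values, idx, axis=0)
    if scheme == "within_samples_joint":
        # One probe permutation shared by every sample; preserves each
        # sample's value multiset but breaks the spatial layout.
        perm = rng.permutation(p)
        return values[:, perm]
    if scheme == "within_samples":
        idx = np.argsort(rng.random((n, p)), axis=1)
        return np.take_along_axis(values, idx, axis=1)
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def split_significance(
    X,
    separator: Separator,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "across_samples",
) -> SignificanceResult:
    """Normal-tail permutation p-value for the separation of two groups.

    For each of ``n_perm`` rounds the probe values are shuffled
    (``scheme`` selects how; see :func:`_shuffled`), the frozen
    separator is re-applied to define two random groups, and their
    centroid distance is recorded (0 when a group is empty).  A normal
    distribution is fitted to the null distances by moments and
    ``p = 1 - Phi((observed - mean)/sd)``.
    """
    values = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, float)
    if separator.labels is None:
        labels = separator.assign_labels(values)
    else:
        labels = np.asarray(separator.labels)
    pos = labels == 1
    if pos.all() or (~pos).all():
        return SignificanceResult(
            observed_distance=0.0, null_mean=float("nan"), null_sd=float("nan"),
            p_value=1.0, n_perm=0, degenerate=True,
        )

    observed = float(np.linalg.norm(centroid(values, pos) - centroid(values, ~pos)))

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for k in range(n_perm):
        shuffled = _shuffled(values, rng, scheme)
        side = separator.decision_values(shuffled) >= 0.0
        if side.all() or (~side).all():
            null[k] = 0.0
            continue
        null[k] = np.linalg.norm(
            np.median(shuffled[side], axis=0) - np.median(shuffled[~side], axis=0)
        )

    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    if sd == 0.0:
        return SignificanceResult(
            observed_distance=observed, null_mean=mu, null_sd=0.0,
            p_value=0.0 if observed > mu else 1.0, n_perm=n_perm, degenerate=True,
        )
    p = float(norm.sf((observed - mu) / sd))
    return SignificanceResult(
        observed_distance=observed, null_mean=mu, null_sd=sd,
        p_value=p, n_perm=n_perm,
    )
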