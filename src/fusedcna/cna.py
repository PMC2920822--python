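"""Discrete CNA calls from cluster centroids and co-occurrence testing.

A cluster's centroid (median profile) is summarized into gain/loss
calls by finding maximal runs of consecutive probes, within one
chromosomal arm, whose centroid values all exceed an amplitude
threshold.  Pairwise co-occurrence of calls across samples is tested
with a one-sided (enrichment) Fisher exact test computed in exact
integer arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .data import CNACall, ProbeMap

__all__ = ["call_cnas", "cooccurrence", "fisher_enrichment_pvalue"]


def call_cnas(
    centroid: np.ndarray,
    probe_map: ProbeMap,
    amp_threshold: float = 0.2,
    min_probes: int = 5,
    node_id: str = "",
    n_samples: int = 0,
) -> list[CNACall]:
    """Threshold-and-run CNA calling on a centroid profile.

    Emits one call per maximal run of at least ``min_probes``
    consecutive probes within a single chromosomal arm whose values all
    exceed ``+amp_threshold`` (gain) or all fall below
    ``-amp_threshold`` (loss); ``mean_amplitude`` is the centroid mean
    over the run.  Calls therefore never cross arm boundaries and are
    returned sorted and disjoint.
    """
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (len(probe_map),):
        raise ValueError("centroid length must match the probe map")
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    state = np.zeros(len(probe_map), dtype=int)
    state[centroid > amp_threshold] = 1
    state[centroid < -amp_threshold] = -1

    calls: list[CNACall] = []
    for chrom, _, seg_start, seg_stop in probe_map.arm_segments():
        run_start = seg_start
        for j in range(seg_start + 1, seg_stop + 1):
            if j < seg_stop and state[j] == state[run_start]:
                continue
            if state[run_start] != 0 and j - run_start >= min_probes:
                calls.append(
                    CNACall(
                        chromosome=chrom,
                        start_probe=run_start,
                        end_probe=j - 1,
                        start_bp=int(probe_map.position[run_start]),
                        end_bp=int(probe_map.position[j - 1]),
                        direction="gain" if state[run_start] > 0 else "loss",
                        mean_amplitude=float(centroid[run_start:j].mean()),
                        node_id=node_id,
                        n_samples=n_samples,
                    )
                )
            run_start = j
    return calls


def fisher_enrichment_pvalue(n_both: int, n_a_only: int, n_b_only: int, n_neither: int) -> float:
    """One-sided Fisher exact p-value for enrichment of joint membership.

    Upper tail of the hypergeometric distribution of the 2x2 table
    ``[[n_both, n_a_only], [n_b_only, n_neither]]`` at the observed
    co-membership count, evaluated in exact rational arithmetic before
    the final float conversion.
    """
    a, b, c, d = n_both, n_a_only, n_b_only, n_neither
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    k_max = min(row1, col1)
    k_min = max(0, col1 - (n - row1))
    total = Fraction(0)
    for k in range(a, k_max + 1):
        if k < k_min:
            continue
        total += Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
    return float(min(total, Fraction(1)))


def cooccurrence(assignments: pd.DataFrame) -> pd.DataFrame:
    """Pairwise enrichment of CNA co-membership across samples.

    ``assignments`` is a boolean samples x CNAs table.  For every
    unordered pair the 2x2 contingency table of joint membership is
    built over all samples and the one-sided Fisher p-value reported.
    Pairs involving a CNA present in all or in no samples are degenerate
    (the margin is fixed) and get ``p = 1`` with a flag.
    """
    if assignments.shape[1] < 2:
        raise ValueError("co-occurrence needs at least two CNAs")
    if assignments.shape[0] < 1:
        raise ValueError("co-occurrence needs at least one sample")
    flags = assignments.astype(bool)
    n = len(flags)
    records = []
    for name_a, name_b in combinations(flags.columns, 2):
        in_a = flags[name_a].to_numpy()
        in_b = flags[name_b].to_numpy()
        both = int(np.sum(in_a & in_b))
        a_only = int(np.sum(in_a & ~in_b))
        b_only = int(np.sum(~in_a & in_b))
        neither = n - both - a_only - b_only
        degenerate = in_a.all() or in_b.all() or (not in_a.any()) or (not in_b.any())
        if degenerate:
            p = 1.0
        else:
            p = fisher_enrichment_pvalue(both, a_only, b_only, neither)
        records.append(
            {
                "cna_a": name_a,
                "cna_b": name_b,
                "n_both": both,
                "n_a_only": a_only,
                "n_b_only": b_only,
                "n_neither": neither,
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame.from_records(records)
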