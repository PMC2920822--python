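"""Statsmodels-style front end: a model fitted to a cohort of profiles.

:class:`RecurrentCNAModel` holds the data and the analysis settings;
:meth:`RecurrentCNAModel.fit` runs the per-chromosome iterative
partitioning and returns a :class:`RecurrentCNAResults` carrying the
partition trees, per-node significance, centroid CNA calls and the
co-occurrence analysis, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna import call_cnas, cooccurrence
from .data import CNACall, ProfileMatrix, read_profiles
from .qp import FusedLassoParams
from .significance import centroid
from .tree import PartitionTree, TreeParams, build_tree

__all__ = ["RecurrentCNAModel", "RecurrentCNAResults"]


class RecurrentCNAModel:
    """Segmentation-free recurrent-CNA discovery on an aCGH cohort.

    Parameters
    ----------
    profiles : ProfileMatrix
        The cohort (samples x probes log2 ratios with probe annotation).
    s1, s2 : float
        Sparseness and piecewise-constantness budgets of the fused-lasso
        separator.
    min_group_size, max_depth, p_threshold, n_perm : stopping rules and
        permutation-test settings of the partition tree.
    weight_form : fusion weight form ("inverse_median" or "uniform").
    """

    def __init__(
        self,
        profiles: ProfileMatrix,
        s1: float = 2.0,
        s2: float = 1.0,
        min_group_size: int = 5,
        max_depth: int = 3,
        p_threshold: float = 0.1,
        n_perm: int = 1000,
        weight_form: str = "inverse_median",
        permutation_scheme: str = "across_samples",
    ):
        self.profiles = profiles
        self.weight_form = weight_form
        self.tree_params = TreeParams(
            min_group_size=min_group_size,
            max_depth=max_depth,
            p_threshold=p_threshold,
            fused=FusedLassoParams(s1=s1, s2=s2),
            n_perm=n_perm,
            permutation_scheme=permutation_scheme,
        )

    @classmethod
    def from_files(cls, matrix_path, annotation_path, missing_policy="impute", **kwargs):
        """Build the model straight from the TSV matrix + annotation files."""
        return cls(read_profiles(matrix_path, annotation_path, missing_policy), **kwargs)

    def fit(self, seed: int = 0, chromosomes: list[str] | None = None) -> "RecurrentCNAResults":
        """Run the per-chromosome iterative partitioning."""
        available = self.profiles.probe_map.chromosomes
        if chromosomes is None:
            chromosomes = available
        else:
            unknown = set(chromosomes) - set(available)
            if unknown:
                raise KeyError(f"chromosomes not in the probe map: {sorted(unknown)}")
        trees = {}
        for chrom in chromosomes:
            sub = self.profiles.restrict_chromosome(chrom)
            trees[chrom] = build_tree(
                sub, self.tree_params, seed=seed, weight_form=self.weight_form
            )
        return RecurrentCNAResults(model=self, trees=trees, seed=seed)


@dataclass
class RecurrentCNAResults:
    """Fitted partition trees and the analyses derived from them."""

    model: RecurrentCNAModel
    trees: dict[str, PartitionTree]
    seed: int
    _calls_cache: dict = field(default_factory=dict, repr=False)

    def node_table(self) -> pd.DataFrame:
        """One row per tree node: size, depth, p-value, stop reason."""
        rows = []
        for chrom, tree in self.trees.items():
            for node in tree.nodes():
                rows.append(
                    {
                        "chromosome": chrom,
                        "node_id": node.node_id,
                        "depth": node.depth,
                        "n_samples": node.n_samples,
                        "p_value": (
                            np.nan if node.significance is None
                            else node.significance.p_value
                        ),
                        "stop_reason": node.stop_reason,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Text summary of the fitted partition, statsmodels-style."""
        params = self.model.tree_params
        table = self.node_table()
        n_splits = int((table["stop_reason"] == "split").sum())
        lines = [
            "Recurrent CNA partition results",
            "=" * 64,
            f"cohort: {self.model.profiles.n_samples} samples x "
            f"{self.model.profiles.n_probes} probes, "
            f"{len(self.trees)} chromosome(s)",
            f"budgets: s1={params.fused.s1}  s2={params.fused.s2}  "
            f"p_threshold={params.p_threshold}  n_perm={params.n_perm}",
            f"stopping: min_group_size={params.min_group_size}  "
            f"max_depth={params.max_depth}",
            f"seed: {self.seed}   significant splits: {n_splits}",
            "-" * 64,
            table.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)

    def cluster_centroid(self, chromosome: str, node_id: str) -> np.ndarray:
        """Median profile of the samples of one tree node."""
        tree = self.trees[chromosome]
        node = next(n for n in tree.nodes() if n.node_id == node_id)
        sub = self.model.profiles.restrict_chromosome(chromosome)
        mask = np.isin(np.asarray(sub.sample_ids, dtype=object), node.sample_ids)
        return centroid(sub, mask)

    def cna_calls(self, amp_threshold: float = 0.2, min_probes: int = 5) -> list[CNACall]:
        """Threshold-based CNA calls on the centroid of every leaf cluster.

        Each leaf of each chromosome tree contributes the calls of its
        centroid; the root is skipped when it was split (its children
        describe the cohort structure better than the global median).
        """
        key = (amp_threshold, min_probes)
        if key in self._calls_cache:
            return self._calls_cache[key]
        calls: list[CNACall] = []
        for chrom, tree in self.trees.items():
            sub = self.model.profiles.restrict_chromosome(chrom)
            ids = np.asarray(sub.sample_ids, dtype=object)
            for node in tree.leaves():
                mask = np.isin(ids, node.sample_ids)
                calls.extend(
                    call_cnas(
                        centroid(sub, mask),
                        sub.probe_map,
                        amp_threshold=amp_threshold,
                        min_probes=min_probes,
                        node_id=f"{chrom}:{node.node_id}",
                        n_samples=node.n_samples,
                    )
                )
        self._calls_cache[key] = calls
        return calls

    def cna_membership(self, amp_threshold: float = 0.2, min_probes: int = 5) -> pd.DataFrame:
        """Boolean samples x CNAs table from the leaf cluster memberships."""
        calls = self.cna_calls(amp_threshold, min_probes)
        samples = self.model.profiles.sample_ids
        columns = {}
        for call in calls:
            chrom, node_id = call.node_id.split(":")
            node = next(
                n for n in self.trees[chrom].nodes() if n.node_id == node_id
            )
            name = (
                f"{call.direction}_{call.chromosome}:{call.start_bp}-{call.end_bp}"
                f"@{call.node_id}"
            )
            members = set(node.sample_ids)
            columns[name] = [s in members for s in samples]
        return pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))

    def cooccurrence(self, amp_threshold: float = 0.2, min_probes: int = 5) -> pd.DataFrame:
        """Pairwise Fisher enrichment of CNA co-membership across samples."""
        return cooccurrence(self.cna_membership(amp_threshold, min_probes))

    def plot_centroids(self, chromosome: str, ax=None):
        """Leaf centroids of one chromosome, offset vertically per cluster."""
        import matplotlib.pyplot as plt

        tree = self.trees[chromosome]
        sub = self.model.profiles.restrict_chromosome(chromosome)
        ids = np.asarray(sub.sample_ids, dtype=object)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        positions = sub.probe_map.position
        for offset, node in enumerate(tree.leaves()):
            mask = np.isin(ids, node.sample_ids)
            ax.plot(
                positions,
                centroid(sub, mask) + 2.0 * offset,
                lw=0.8,
                label=f"{node.node_id} (n={node.n_samples})",
            )
        ax.set_xlabel("position (bp)")
        ax.set_ylabel("median log2 ratio (offset per cluster)")
        ax.set_title(f"chromosome {chromosome} leaf centroids")
        ax.legend(fontsize="small")
        return ax
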