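"""Hierarchical divisive partitioning of a cohort on one chromosome.

Starting from the full cohort, each group is split in two by
maximum-margin clustering; the weight vector of every new separator is
constrained orthogonal to those of its ancestors, so successive splits
explore new directions of copy-number variation (analogous to principal
components).  A split is kept only if the group is large enough, the
tree is not at maximal depth, and a probe-shuffling permutation test
deems the separation significant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .data import ProfileMatrix
from .mmc import MMCResult, mmc_partition
from .qp import FusedLassoParams, FusionWeights, Separator, compute_fusion_weights
from .significance import SignificanceResult, split_significance

__all__ = [
    "PartitionNode",
    "PartitionTree",
    "TreeParams",
    "build_tree",
    "read_tree",
    "write_node_summary",
    "write_tree",
]


@dataclass(frozen=True)
class TreeParams:
    """Stopping rules and per-split settings of the partition tree.

    A group is considered for splitting only if it holds more than
    ``min_group_size`` samples and sits above ``max_depth``; a candidate
    split is kept only if its permutation p-value is at most
    ``p_threshold``.
    """

    min_group_size: int = 5
    max_depth: int = 3
    p_threshold: float = 0.1
    fused: FusedLassoParams = field(default_factory=FusedLassoParams)
    n_perm: int = 1000
    permutation_scheme: str = "across_samples"

    def __post_init__(self):
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class PartitionNode:
    """One group of samples in the partition tree.

    Internal nodes carry the separator that produced their two children
    and its significance; leaves record why they were not split.
    """

    node_id: str
    sample_ids: list[str]
    depth: int
    separator: Separator | None = None
    significance: SignificanceResult | None = None
    children: list["PartitionNode"] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["PartitionNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PartitionTree:
    chromosome: str
    root: PartitionNode
    params: TreeParams
    seed: int

    def nodes(self) -> list[PartitionNode]:
        return list(self.root.walk())

    def leaves(self) -> list[PartitionNode]:
        return [node for node in self.root.walk() if node.is_leaf]


def node_seed(root_seed: int, path: str) -> int:
    """Deterministic per-node seed derived from the root seed and node path."""
    digest = hashlib.blake2b(f"{root_seed}:{path}".encode(), digest_size=4)
    return int.from_bytes(digest.digest(), "big") % (2**31)


def build_tree(
    X: ProfileMatrix,
    params: TreeParams,
    seed: int = 0,
    weights: FusionWeights | None = None,
    weight_form: str = "inverse_median",
) -> PartitionTree:
    """Recursively partition the cohort of a single chromosome.

    Each node derives its own seed from ``seed`` and its path, so the
    tree is reproducible and sibling subtrees are independent.  A
    failure inside one node (solver breakdown) turns that node into a
    leaf with ``stop_reason='failure'`` without aborting its siblings.
    """
    chromosomes = X.probe_map.chromosomes
    if len(chromosomes) != 1:
        raise ValueError(
            "build_tree analyzes one chromosome at a time; restrict the matrix first"
        )
    if X.n_samples < 2:
        raise ValueError("need at least 2 samples to build a tree")
    if weights is None:
        weights = compute_fusion_weights(X.probe_map, form=weight_form)

    def grow(indices: np.ndarray, depth: int, path: str, ancestors: list) -> PartitionNode:
        node = PartitionNode(
            node_id=path,
            sample_ids=[X.sample_ids[i] for i in indices],
            depth=depth,
        )
        if len(indices) <= params.min_group_size:
            node.stop_reason = "too_small"
            return node
        if depth >= params.max_depth:
            node.stop_reason = "max_depth"
            return node
        sub = X.subset_samples(indices)
        local_seed = node_seed(seed, path)
        try:
            result: MMCResult = mmc_partition(
                sub,
                FusedLassoParams(
                    params.fused.s1, params.fused.s2, params.fused.max_iter, local_seed
                ),
                weights,
                orthogonal_to=ancestors,
            )
            if result.trivial:
                node.separator = result.separator
                node.stop_reason = "not_significant"
                return node
            significance = split_significance(
                sub,
                result.separator,
                n_perm=params.n_perm,
                seed=node_seed(seed, path + "#perm"),
                scheme=params.permutation_scheme,
            )
        except Exception:
            node.stop_reason = "failure"
            return node
        node.separator = result.separator
        node.significance = significance
        if significance.p_value > params.p_threshold:
            node.stop_reason = "not_significant"
            return node
        node.stop_reason = "split"
        labels = result.separator.labels
        next_ancestors = ancestors + [result.separator.beta]
        for side, tag in ((1, "+"), (-1, "-")):
            child_idx = indices[labels == side]
            node.children.append(grow(child_idx, depth + 1, path + tag, next_ancestors))
        return node

    root = grow(np.arange(X.n_samples), 0, "r", [])
    return PartitionTree(chromosome=chromosomes[0], root=root, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Serialization: a lossless JSON representation of the tree.

def _separator_to_json(sep: Separator | None):
    if sep is None:
        return None
    return {
        "beta": [float(v) for v in sep.beta],
        "bias": float(sep.bias),
        "labels": None if sep.labels is None else [int(v) for v in sep.labels],
    }


def _separator_from_json(doc):
    if doc is None:
        return None
    labels = None if doc["labels"] is None else np.asarray(doc["labels"], dtype=int)
    return Separator(np.asarray(doc["beta"], dtype=float), doc["bias"], labels)


def _significance_to_json(sig: SignificanceResult | None):
    if sig is None:
        return None
    return {
        "observed_distance": sig.observed_distance,
        "null_mean": sig.null_mean,
        "null_sd": sig.null_sd,
        "p_value": sig.p_value,
        "n_perm": sig.n_perm,
        "degenerate": sig.degenerate,
    }


def _significance_from_json(doc):
    if doc is None:
        return None
    return SignificanceResult(**doc)


def _node_to_json(node: PartitionNode):
    return {
        "node_id": node.node_id,
        "sample_ids": node.sample_ids,
        "depth": node.depth,
        "stop_reason": node.stop_reason,
        "separator": _separator_to_json(node.separator),
        "significance": _significance_to_json(node.significance),
        "children": [_node_to_json(child) for child in node.children],
    }


def _node_from_json(doc) -> PartitionNode:
    return PartitionNode(
        node_id=doc["node_id"],
        sample_ids=list(doc["sample_ids"]),
        depth=doc["depth"],
        separator=_separator_from_json(doc["separator"]),
        significance=_significance_from_json(doc["significance"]),
        children=[_node_from_json(child) for child in doc["children"]],
        stop_reason=doc["stop_reason"],
    )


def write_tree(tree: PartitionTree, path, provenance: dict | None = None) -> None:
    """Serialize the tree to JSON; the round trip is lossless to full precision."""
    doc = {
        "chromosome": tree.chromosome,
        "seed": tree.seed,
        "params": {
            "min_group_size": tree.params.min_group_size,
            "max_depth": tree.params.max_depth,
            "p_threshold": tree.params.p_threshold,
            "n_perm": tree.params.n_perm,
            "permutation_scheme": tree.params.permutation_scheme,
            "fused": {
                "s1": tree.params.fused.s1,
                "s2": tree.params.fused.s2,
                "max_iter": tree.params.fused.max_iter,
                "seed": tree.params.fused.seed,
            },
        },
        "provenance": provenance or {},
        "root": _node_to_json(tree.root),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_tree(path) -> PartitionTree:
    with open(path) as fh:
        doc = json.load(fh)
    fused = FusedLassoParams(**doc["params"]["fused"])
    params = TreeParams(
        min_group_size=doc["params"]["min_group_size"],
        max_depth=doc["params"]["max_depth"],
        p_threshold=doc["params"]["p_threshold"],
        fused=fused,
        n_perm=doc["params"]["n_perm"],
        permutation_scheme=doc["params"]["permutation_scheme"],
    )
    return PartitionTree(
        chromosome=doc["chromosome"],
        root=_node_from_json(doc["root"]),
        params=params,
        seed=doc["seed"],
    )


def write_node_summary(trees, path, provenance: dict | None = None) -> None:
    """Per-node TSV: chromosome, node id, depth, size, p-value, stop reason."""
    if isinstance(trees, PartitionTree):
        trees = [trees]
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}={value}\n")
        fh.write("chromosome\tnode_id\tdepth\tn_samples\tp_value\tstop_reason\n")
        for tree in trees:
            for node in tree.nodes():
                p = "" if node.significance is None else repr(node.significance.p_value)
                fh.write(
                    f"{tree.chromosome}\t{node.node_id}\t{node.depth}\t"
                    f"{node.n_samples}\t{p}\t{node.stop_reason}\n"
                )
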