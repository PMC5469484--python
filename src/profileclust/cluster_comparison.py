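"""Gene-level cluster membership, cross-condition matching and overlaps.

Clustering operates on TSS anchors, but biology is reported per gene: a
gene belongs to every cluster that any of its retained anchors was assigned
to (genes with multiple TSS can therefore sit in several clusters).
Clusters from two independent runs (e.g. undifferentiated vs differentiated
cells) are paired by the gene-overlap-maximising bipartite assignment;
stability of a cluster is the fraction of its genes that land in the
matched cluster of the other condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .annotations import TssAnchor
from .errors import ValidationError
from .profile_clustering import ClusterResult
from . import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneClusterMembership",
    "ClusterMatch",
    "gene_membership",
    "cluster_gene_sets",
    "match_clusters",
    "set_overlap_test",
    "stable_core",
]

GeneClusterMembership = dict[str, set[int]]


@dataclass
class ClusterMatch:
    """Optimal pairing of cluster labels between two conditions."""

    mapping: dict[int, int]  # cluster label in A -> matched label in B
    stability: dict[int, float]  # fraction of A-cluster genes staying in the match
    overlap_matrix: np.ndarray  # k x k gene counts, rows = A, cols = B


def gene_membership(result: ClusterResult, anchors: Sequence[TssAnchor]) -> GeneClusterMembership:
    """Union of anchor labels per gene: gene in cluster c iff any anchor has label c."""
    if len(result.labels) != len(anchors):
        raise ValidationError("labels are not aligned to anchors")
    membership: GeneClusterMembership = {}
    for label, anchor in zip(result.labels, anchors):
        for gene in anchor.gene_ids:
            membership.setdefault(gene, set()).add(int(label))
    return membership


def cluster_gene_sets(membership: GeneClusterMembership, k: int) -> list[set[str]]:
    """Gene set per cluster label 1..k (index c-1)."""
    sets: list[set[str]] = [set() for _ in range(k)]
    for gene, labels in membership.items():
        for c in labels:
            if not 1 <= c <= k:
                raise ValidationError(f"label {c} outside 1..{k}")
            sets[c - 1].add(gene)
    return sets


def match_clusters(
    membership_a: GeneClusterMembership, membership_b: GeneClusterMembership, k: int
) -> ClusterMatch:
    """Pair clusters across conditions by overlap-maximal bipartite assignment.

    With canonical relabelling the expected mapping is the identity; any
    deviation is logged because it usually signals an unstable partition.
    """
    sets_a = cluster_gene_sets(membership_a, k)
    sets_b = cluster_gene_sets(membership_b, k)
    overlap = np.array([[len(a & b) for b in sets_b] for a in sets_a], dtype=int)
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}
    if any(a != b for a, b in mapping.items()):
        logger.warning("cluster matching deviates from identity: %s", mapping)
    stability = {}
    for c_a, c_b in mapping.items():
        denom = len(sets_a[c_a - 1])
        stability[c_a] = (
            len(sets_a[c_a - 1] & sets_b[c_b - 1]) / denom if denom else float("nan")
        )
    return ClusterMatch(mapping=mapping, stability=stability, overlap_matrix=overlap)


def set_overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p-value for two gene sets."""
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not (set_a <= universe and set_b <= universe):
        raise ValidationError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = stats.hypergeometric_tail(k, len(set_a), len(set_b), len(universe))
    return k, p


def stable_core(genesets: Sequence[Iterable[str]]) -> set[str]:
    """Exact intersection of two or more gene sets."""
    if len(genesets) < 2:
        raise ValidationError("need at least two gene sets to intersect")
    core = set(genesets[0])
    for s in genesets[1:]:
        core &= set(s)
    return core
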