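"""Measure how stable each profile cluster is across differentiation.

Clusters one histone mark independently in both conditions, pairs the
clusters by overlap-maximising assignment and prints the per-cluster
stability: the fraction of a cluster's genes found in the matched cluster
of the other condition.
"""

import tempfile

from profileclust import (
    build_signal_matrix,
    canonical_relabel,
    collapse_tss,
    deduplicate_transcripts,
    filter_by_length,
    gene_membership,
    kmeans_profiles,
    match_clusters,
    read_coverage,
    read_gene_models,
    subtract_input_and_filter,
)
from profileclust.synthetic_data import simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    ds = simulate_dataset(tmp, seed=3)
    transcripts = deduplicate_transcripts(read_gene_models(ds.annotation, "bed12"))
    anchors = collapse_tss(filter_by_length(transcripts))

    memberships = {}
    for cond in ("undiff", "diff"):
        sample = build_signal_matrix(read_coverage(ds.coverage[("H3K4me2", cond)]), anchors)
        control = build_signal_matrix(read_coverage(ds.inputs[cond]), anchors)
        matrix = subtract_input_and_filter(sample, control)
        clusters = canonical_relabel(kmeans_profiles(matrix, k=6, seed=3), matrix)
        memberships[cond] = gene_membership(clusters, matrix.anchors)

    match = match_clusters(memberships["undiff"], memberships["diff"], k=6)
    print("cluster pairing (undiff -> diff):", match.mapping)
    for c in sorted(match.stability):
        print(f"  cluster {c}: stability {match.stability[c]:.2f}")
    print("planted cluster-1 stability was 0.85; the estimate for cluster 1 above")
    print("should sit within sampling noise of it. Low-signal clusters are")
    print("intrinsically less stable: their genes sit near the filter boundary.")
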