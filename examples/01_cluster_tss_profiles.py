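"""Cluster TSS-centred histone-mark profiles into shape classes.

Simulates a small two-condition ChIP experiment, builds the -2 kb/+4 kb
binned signal matrix around every TSS, subtracts the matched input, runs
seeded k-means (k=6) and prints the canonical cluster sizes next to the
planted archetype sizes, plus the adjusted Rand index between them.
"""

import tempfile

import numpy as np
from sklearn.metrics import adjusted_rand_score

from profileclust import (
    build_signal_matrix,
    canonical_relabel,
    collapse_tss,
    deduplicate_transcripts,
    filter_by_length,
    kmeans_profiles,
    read_coverage,
    read_gene_models,
    subtract_input_and_filter,
)
from profileclust.synthetic_data import SimulationParams, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    ds = simulate_dataset(tmp, seed=17, params=SimulationParams(n_genes=300))
    transcripts = deduplicate_transcripts(read_gene_models(ds.annotation, "bed12"))
    anchors = collapse_tss(filter_by_length(transcripts, min_length=4000))
    sample = build_signal_matrix(read_coverage(ds.coverage[("H3K4me2", "undiff")]), anchors)
    control = build_signal_matrix(read_coverage(ds.inputs["undiff"]), anchors)
    matrix = subtract_input_and_filter(sample, control)
    result = canonical_relabel(kmeans_profiles(matrix, k=6, seed=17), matrix)

    truth = [
        ds.truth["genes"][sorted(a.gene_ids)[0]]["archetype"]["H3K4me2"]["undiff"]
        for a in matrix.anchors
    ]
    print(f"anchors: {len(anchors)} derived, {len(matrix)} retained after input subtraction")
    print("cluster sizes (canonical 1..6):", result.cluster_sizes().tolist())
    print("planted archetype sizes      :", np.bincount(truth, minlength=7)[1:].tolist())
    print(f"adjusted Rand index vs planted labels: {adjusted_rand_score(truth, result.labels):.3f}")
    print("ARI near 1 means k-means recovered the planted profile-shape classes;")
    print("cluster 1 is the gene-body-enriched class, cluster 6 the low-signal class.")
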