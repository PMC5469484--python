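"""End-to-end orchestration: anchors -> matrices -> clustering -> integration.

`run_pipeline` executes the whole analysis for two marks x two conditions,
writes every intermediate table as TSV plus a machine-readable manifest
(with row counts at each filter, reproducing the analysis funnel), and
returns the in-memory results for programmatic use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import (
    collapse_tss,
    deduplicate_transcripts,
    filter_by_length,
    read_gene_models,
    write_anchor_bed,
)
from .cluster_comparison import (
    cluster_gene_sets,
    gene_membership,
    match_clusters,
    set_overlap_test,
    stable_core,
)
from .coverage import read_coverage
from .errors import ValidationError
from .expression_integration import (
    call_differential,
    cluster_expression_compare,
    integrate,
    read_expression_table,
)
from .motif_scan import genes_with_motif, scan_peaks
from .peak_integration import (
    assign_peaks_to_genes,
    classify_dynamics,
    cluster_binding_enrichment,
    read_narrowpeak,
)
from .profile_clustering import canonical_relabel, kmeans_profiles
from .signal_matrix import WindowSpec, build_signal_matrix, subtract_input_and_filter
from . import stats as pcstats
from .synthetic_data import CONDITIONS, MARKS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineInputs", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline with their standard defaults."""

    min_transcript_len: int = 4000
    window: WindowSpec = field(default_factory=WindowSpec)
    k: int = 6
    kmeans_max_iter: int = 1_000_000
    kmeans_restarts: int = 10
    peak_upstream: int = 10_000
    motif_window: int = 30
    patterns: tuple = ("CANNTG", "CAGCTG")
    fc_threshold: float = 2.0
    pseudocount: float = 1.0
    enrichment_alpha: float = 0.01
    seed: int = 17
    clamp_negative: bool = False
    row_normalize: bool = False
    summit_only: bool = False
    annotation_format: str = "bed12"

    def __post_init__(self) -> None:
        if min(self.min_transcript_len, self.k, self.kmeans_restarts,
               self.peak_upstream, self.motif_window) <= 0:
            raise ValidationError("all pipeline thresholds must be positive")


@dataclass
class PipelineInputs:
    """File-system inputs of one run; marks and conditions label the layers."""

    annotation: Path
    genome: Path
    coverage: dict  # (mark, condition) -> bedGraph path
    inputs: dict  # condition -> bedGraph path
    peaks: dict  # condition -> narrowPeak path
    expression: Path
    gene_sets: Path | None = None  # optional GMT for enrichment reporting
    marks: tuple = MARKS
    conditions: tuple = CONDITIONS

    @classmethod
    def from_simulation(cls, dataset_dir: str | Path) -> "PipelineInputs":
        """Locate the files written by :func:`synthetic_data.simulate_dataset`."""
        d = Path(dataset_dir)
        return cls(
            annotation=d / "genes.bed",
            genome=d / "genome.fa",
            coverage={(m, c): d / f"{m}_{c}.bedGraph" for m in MARKS for c in CONDITIONS},
            inputs={c: d / f"input_{c}.bedGraph" for c in CONDITIONS},
            peaks={c: d / f"myod_{c}.narrowPeak" for c in CONDITIONS},
            expression=d / "expression.tsv",
        )


@dataclass
class PipelineResult:
    anchors: list
    layers: dict  # (mark, cond) -> {"matrix": ..., "clusters": ..., "membership": ...}
    matches: dict  # mark -> ClusterMatch
    common_cluster1: dict  # cond -> gene set (cluster 1 in both marks)
    stable_core: set
    assignments: dict  # cond -> gene -> peak ids
    dynamics: dict
    motif_flags: dict
    expression: pd.DataFrame
    integrated: pd.DataFrame
    funnel: dict
    binding_tables: dict  # cond -> DataFrame
    enrichment: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; write TSV outputs and a manifest if ``outdir`` set."""
    config = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "version": __version__, "counts": {}}
    counts = manifest["counts"]

    # --- annotations ---------------------------------------------------
    transcripts = read_gene_models(inputs.annotation, format=config.annotation_format)
    counts["transcripts_read"] = len(transcripts)
    transcripts = deduplicate_transcripts(transcripts)
    counts["transcripts_unique"] = len(transcripts)
    filtered = filter_by_length(transcripts, config.min_transcript_len)
    counts["transcripts_length_filtered"] = len(filtered)
    anchors = collapse_tss(filtered)
    counts["tss_anchors"] = len(anchors)
    universe = sorted({g for a in anchors for g in a.gene_ids})
    counts["genes_in_universe"] = len(universe)
    if out is not None:
        write_anchor_bed(anchors, out / "anchors.bed")

    # --- signal matrices and clustering, per mark x condition ----------
    input_tracks = {
        c: read_coverage(inputs.inputs[c], "bedGraph", label=f"input_{c}")
        for c in inputs.conditions
    }
    layers: dict = {}
    for mark in inputs.marks:
        for cond in inputs.conditions:
            track = read_coverage(
                inputs.coverage[(mark, cond)], "bedGraph", label=f"{mark}_{cond}"
            )
            sample = build_signal_matrix(track, anchors, config.window)
            control = build_signal_matrix(input_tracks[cond], anchors, config.window)
            matrix = subtract_input_and_filter(sample, control, config.clamp_negative)
            counts[f"retained_{mark}_{cond}"] = len(matrix)
            clusters = canonical_relabel(
                kmeans_profiles(
                    matrix,
                    k=config.k,
                    max_iter=config.kmeans_max_iter,
                    n_restarts=config.kmeans_restarts,
                    seed=config.seed,
                    row_normalize=config.row_normalize,
                ),
                matrix,
            )
            membership = gene_membership(clusters, matrix.anchors)
            layers[(mark, cond)] = {
                "matrix": matrix,
                "clusters": clusters,
                "membership": membership,
            }
            if out is not None:
                pd.DataFrame(
                    {"anchor": matrix.anchor_names, "cluster": clusters.labels}
                ).to_csv(out / f"labels_{mark}_{cond}.tsv", sep="\t", index=False)
                np.savetxt(out / f"centroids_{mark}_{cond}.tsv",
                           clusters.centroids, delimiter="\t")

    # --- cross-condition matching and the stable cluster-1 core --------
    matches = {}
    for mark in inputs.marks:
        a, b = inputs.conditions
        matches[mark] = match_clusters(
            layers[(mark, a)]["membership"], layers[(mark, b)]["membership"], config.k
        )
    cluster1 = {
        (mark, cond): cluster_gene_sets(layers[(mark, cond)]["membership"], config.k)[0]
        for mark in inputs.marks
        for cond in inputs.conditions
    }
    common_cluster1 = {
        cond: stable_core([cluster1[(m, cond)] for m in inputs.marks])
        for cond in inputs.conditions
    }
    overlap_tests = {}
    for cond in inputs.conditions:
        sets = [cluster1[(m, cond)] for m in inputs.marks]
        n, p = set_overlap_test(sets[0], sets[1], universe)
        overlap_tests[cond] = {"overlap": n, "p_value": p}
        counts[f"common_cluster1_{cond}"] = len(common_cluster1[cond])
    core = stable_core(list(common_cluster1.values()))
    counts["stable_core"] = len(core)

    # --- peaks, dynamics, binding enrichment ---------------------------
    assignments = {}
    for cond in inputs.conditions:
        peaks = read_narrowpeak(inputs.peaks[cond])
        counts[f"peaks_{cond}"] = len(peaks)
        assignments[cond] = assign_peaks_to_genes(
            peaks, transcripts, config.peak_upstream, config.summit_only
        )
        counts[f"bound_genes_{cond}"] = len(
            [g for g in universe if assignments[cond].get(g)]
        )
    a_cond, b_cond = inputs.conditions
    dynamics = classify_dynamics(assignments[a_cond], assignments[b_cond], universe)
    binding_tables = {}
    for cond in inputs.conditions:
        bound = {g for g in universe if assignments[cond].get(g)}
        sets_by_mark = {
            m: cluster_gene_sets(layers[(m, cond)]["membership"], config.k)
            for m in inputs.marks
        }
        common_membership: dict[str, set[int]] = {}
        for ci in range(config.k):
            common = set.intersection(*(sets_by_mark[m][ci] for m in inputs.marks))
            for g in common:
                common_membership.setdefault(g, set()).add(ci + 1)
        binding_tables[cond] = cluster_binding_enrichment(
            common_membership, bound, universe, config.k
        )

    # --- motifs under gained summits ------------------------------------
    gained_peaks = read_narrowpeak(inputs.peaks[b_cond])
    hits = scan_peaks(inputs.genome, gained_peaks, config.motif_window, config.patterns)
    counts["motif_hits"] = len(hits)
    motif_flags = genes_with_motif(assignments[b_cond], hits)

    # --- expression and integration ------------------------------------
    expression = call_differential(
        read_expression_table(inputs.expression),
        fc_threshold=config.fc_threshold,
        pseudocount=config.pseudocount,
    )
    memberships = {
        f"{mark}_{cond}": layers[(mark, cond)]["membership"]
        for mark in inputs.marks
        for cond in inputs.conditions
    }
    integrated, funnel = integrate(memberships, core, dynamics, motif_flags, expression)
    counts.update({f"funnel_{k}": v for k, v in funnel.items() if k != "final_genes"})
    mark0 = inputs.marks[0]
    if config.k >= 2:
        u_stat, mw_p = cluster_expression_compare(
            layers[(mark0, a_cond)]["membership"], expression, 1, 2, condition="a"
        )
        manifest["cluster1_vs_2_expression"] = {"U": u_stat, "p_value": mw_p}
    manifest["cluster1_mark_overlap"] = overlap_tests
    manifest["stability"] = {
        mark: matches[mark].stability for mark in inputs.marks
    }
    manifest["funnel"] = funnel

    enrichment = None
    if inputs.gene_sets is not None:
        refs = pcstats.read_gmt(inputs.gene_sets)
        refs = {name: s & set(universe) for name, s in refs.items()}
        enrichment = pcstats.gene_set_enrichment(
            core, refs, universe, alpha=config.enrichment_alpha
        )

    # --- outputs --------------------------------------------------------
    if out is not None:
        _write_outputs(out, inputs, layers, matches, dynamics, assignments,
                       motif_flags, expression, integrated, funnel,
                       binding_tables, enrichment)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)

    return PipelineResult(
        anchors=anchors,
        layers=layers,
        matches=matches,
        common_cluster1=common_cluster1,
        stable_core=core,
        assignments=assignments,
        dynamics=dynamics,
        motif_flags=motif_flags,
        expression=expression,
        integrated=integrated,
        funnel=funnel,
        binding_tables=binding_tables,
        enrichment=enrichment,
        manifest=manifest,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["window"] = [config.window.upstream_bp, config.window.downstream_bp,
                   config.window.bin_bp]
    return d


def _write_outputs(out, inputs, layers, matches, dynamics, assignments, motif_flags,
                   expression, integrated, funnel, binding_tables, enrichment) -> None:
    rows = []
    for (mark, cond), layer in layers.items():
        for gene, labels in sorted(layer["membership"].items()):
            rows.append((gene, mark, cond, ",".join(map(str, sorted(labels)))))
    pd.DataFrame(rows, columns=["gene_id", "mark", "condition", "clusters"]).to_csv(
        out / "membership.tsv", sep="\t", index=False
    )
    for mark, match in matches.items():
        pd.DataFrame(
            {
                "cluster_a": list(match.mapping),
                "cluster_b": list(match.mapping.values()),
                "stability": [match.stability[c] for c in match.mapping],
            }
        ).to_csv(out / f"stability_{mark}.tsv", sep="\t", index=False)
    for cond, assign in assignments.items():
        pd.DataFrame(
            [(g, ",".join(sorted(p))) for g, p in sorted(assign.items())],
            columns=["gene_id", "peak_ids"],
        ).to_csv(out / f"assignment_{cond}.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(dynamics.items()), columns=["gene_id", "dynamics"]).to_csv(
        out / "dynamics.tsv", sep="\t", index=False
    )
    for cond, table in binding_tables.items():
        table.to_csv(out / f"cluster_binding_{cond}.tsv", sep="\t", index=False)
    expression.to_csv(out / "expression_called.tsv", sep="\t", index=False)
    integrated.to_csv(out / "integrated.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(k, v) for k, v in funnel.items() if k != "final_genes"]
        + [("final_genes", ",".join(funnel["final_genes"]))],
        columns=["stage", "value"],
    ).to_csv(out / "funnel.tsv", sep="\t", index=False)
    if enrichment is not None:
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
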