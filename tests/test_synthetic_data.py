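"""Generator determinism, planted structure and self-consistency."""

import collections
import filecmp

import numpy as np
import pytest
from pyfaidx import Fasta

from profileclust.annotations import (
    collapse_tss,
    deduplicate_transcripts,
    filter_by_length,
    read_gene_models,
)
from profileclust.coverage import read_coverage
from profileclust.errors import GenerationError
from profileclust.expression_integration import call_differential, read_expression_table
from profileclust.motif_scan import extract_summit_window, scan_ebox
from profileclust.peak_integration import assign_peaks_to_genes, read_narrowpeak
from profileclust.signal_matrix import build_signal_matrix, subtract_input_and_filter
from profileclust.synthetic_data import (
    SimulationParams,
    archetype_shapes,
    generate_genome_and_annotation,
    simulate_dataset,
)

SMALL = dict(n_genes=80, n_chroms=1, chrom_length=2_500_000, n_repressed_targets=3)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a = simulate_dataset(tmp_path / "a", 3, SimulationParams(**SMALL))
        b = simulate_dataset(tmp_path / "b", 3, SimulationParams(**SMALL))
        for name in ("genome.fa", "genes.bed", "expression.tsv", "truth.json",
                     "H3K4me2_undiff.bedGraph", "myod_diff.narrowPeak"):
            assert filecmp.cmp(a.outdir / name, b.outdir / name, shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_dataset(tmp_path / "a", 3, SimulationParams(**SMALL))
        b = simulate_dataset(tmp_path / "b", 4, SimulationParams(**SMALL))
        assert not filecmp.cmp(a.outdir / "genome.fa", b.outdir / "genome.fa",
                               shallow=False)


class TestAnnotationStructure:
    def test_short_gene_fraction_within_three_sigma(self, dataset17):
        genes = dataset17.truth["genes"]
        n = len(genes)
        short = sum(g["length"] < 4000 for g in genes.values())
        p = 0.10
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(short - n * p) < 3 * sigma

    def test_genes_do_not_overlap(self, dataset17):
        by_chrom = collections.defaultdict(list)
        for g in dataset17.truth["genes"].values():
            by_chrom[g["chrom"]].append((g["start"], g["end"]))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2

    def test_stable_fraction_one_freezes_archetypes(self, tmp_path):
        params = SimulationParams(stable_fraction=1.0, **SMALL)
        truth = generate_genome_and_annotation(tmp_path, 5, params)
        for g in truth["genes"].values():
            for mark in ("H3K4me2", "H3K4me3"):
                assert g["archetype"][mark]["undiff"] == g["archetype"][mark]["diff"]

    def test_overcrowded_layout_raises_generation_error(self, tmp_path):
        params = SimulationParams(n_genes=600, n_chroms=1, chrom_length=1_000_000)
        with pytest.raises(GenerationError, match="chrom_length"):
            generate_genome_and_annotation(tmp_path, 1, params)

    def test_annotation_parses_and_collapses(self, dataset17):
        txs = deduplicate_transcripts(read_gene_models(dataset17.annotation, "bed12"))
        anchors = collapse_tss(filter_by_length(txs))
        genes = dataset17.truth["genes"]
        expected = {gid for gid, g in genes.items() if g["length"] >= 4000}
        assert {g for a in anchors for g in a.gene_ids} == expected
        # isoforms share the TSS, so anchors match eligible genes one-to-one
        assert len(anchors) == len(expected)


class TestCoverageStructure:
    def test_archetype_shapes_are_distributions(self):
        shapes = archetype_shapes()
        for shape in shapes.values():
            assert shape.min() >= 0
            assert shape.sum() == pytest.approx(1.0)

    def test_background_only_sample_mostly_filtered(self, tmp_path):
        params = SimulationParams(
            amplitudes={c: 0.0 for c in range(1, 7)}, **SMALL
        )
        ds = simulate_dataset(tmp_path, 9, params)
        txs = deduplicate_transcripts(read_gene_models(ds.annotation, "bed12"))
        anchors = collapse_tss(filter_by_length(txs))
        sample = build_signal_matrix(
            read_coverage(ds.coverage[("H3K4me2", "undiff")]), anchors
        )
        control = build_signal_matrix(read_coverage(ds.inputs["undiff"]), anchors)
        retained = subtract_input_and_filter(sample, control)
        assert len(retained) / len(anchors) < 0.60

    def test_realized_bin_sums_near_expectation(self, dataset17):
        """Per-anchor realised totals stay within Poisson bounds of expectation."""
        params = SimulationParams()
        txs = deduplicate_transcripts(read_gene_models(dataset17.annotation, "bed12"))
        anchors = collapse_tss(filter_by_length(txs))
        track = read_coverage(dataset17.coverage[("H3K4me2", "undiff")])
        genes = dataset17.truth["genes"]
        shapes = archetype_shapes()
        n_bins_genome = sum(v // 100 for v in dataset17.truth["chromosomes"].values())
        bg = params.depth * params.background_fraction / n_bins_genome
        ok = 0
        scale = params.depth / 1e5  # amplitudes are quoted at a 1e5 reference depth
        for a in anchors:
            gid = sorted(a.gene_ids)[0]
            arch = genes[gid]["archetype"]["H3K4me2"]["undiff"]
            lam = params.amplitudes[arch] * scale + bg * 60  # expected window fragments
            got = track.window_sum(a.chrom, a.tss - 4000, a.tss + 4001) / 100
            if abs(got - lam) <= 4 * np.sqrt(lam):
                ok += 1
        assert ok / len(anchors) > 0.98


class TestPeaksAndMotifs:
    def test_bound_sets_nested_and_recovered_exactly(self, dataset17):
        truth = dataset17.truth
        assert set(truth["bound_genes"]["undiff"]) <= set(truth["bound_genes"]["diff"])
        txs = deduplicate_transcripts(read_gene_models(dataset17.annotation, "bed12"))
        for cond in ("undiff", "diff"):
            peaks = read_narrowpeak(dataset17.peaks[cond])
            assign = assign_peaks_to_genes(peaks, txs)
            assert sorted(assign) == truth["bound_genes"][cond]

    def test_planted_preferred_motifs_found_under_summits(self, dataset17):
        genome = Fasta(str(dataset17.genome))
        peaks = {p.peak_id: p for p in read_narrowpeak(dataset17.peaks["diff"])}
        checked = 0
        for gid, g in dataset17.truth["genes"].items():
            if not g["motif"] or not g["motif"]["preferred"]:
                continue
            window = extract_summit_window(genome, peaks[f"diff_pk_{gid}"])
            assert any(h.is_preferred for h in scan_ebox(window))
            checked += 1
        assert checked >= 10

    def test_chance_ebox_rate_matches_analytic(self, dataset17):
        """Degenerate-class hit rate in random DNA ~= 25 x (1/4)^4 per window."""
        rng = np.random.default_rng(0)
        genome = Fasta(str(dataset17.genome))
        chrom = genome["chr1"]
        planted = {
            g["motif"]["position"]
            for g in dataset17.truth["genes"].values()
            if g["motif"]
        }
        n_windows, n_hit_offsets = 10_000, 0
        for _ in range(n_windows):
            start = int(rng.integers(0, len(chrom) - 30))
            if any(start - 30 < pos < start + 30 for pos in planted):
                continue
            seq = str(chrom[start : start + 30]).upper()
            n_hit_offsets += len(scan_ebox(seq, ["CANNTG"]))
        rate = n_hit_offsets / n_windows
        expected = 25 * (1 / 4) ** 4
        assert rate == pytest.approx(expected, rel=0.15)


class TestExpression:
    def test_repressed_targets_called_de_down(self, dataset17):
        expr = call_differential(read_expression_table(dataset17.expression))
        expr = expr.set_index("gene_id")
        for gid in dataset17.truth["repressed_targets"]:
            assert bool(expr.at[gid, "is_de"])
            assert expr.at[gid, "direction"] == "down"

    def test_flat_genes_not_called(self, dataset17):
        expr = call_differential(read_expression_table(dataset17.expression))
        expr = expr.set_index("gene_id")
        for gid, g in dataset17.truth["genes"].items():
            if g["expression_class"] == "flat":
                assert not bool(expr.at[gid, "is_de"])

    def test_archetype1_expression_exceeds_archetype6(self, dataset17):
        from profileclust.stats import mann_whitney_u

        genes = dataset17.truth["genes"]
        hi = [g["fpkm"][0] for g in genes.values()
              if g["archetype"]["H3K4me2"]["undiff"] == 1]
        lo = [g["fpkm"][0] for g in genes.values()
              if g["archetype"]["H3K4me2"]["undiff"] == 6]
        _, p = mann_whitney_u(hi, lo)
        assert p < 1e-6
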