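"""narrowPeak parsing, peak-to-gene assignment and binding dynamics."""

import numpy as np
import pytest

from profileclust.annotations import TranscriptRecord
from profileclust.errors import ParseError, ValidationError
from profileclust.peak_integration import (
    Peak,
    assign_peaks_to_genes,
    classify_dynamics,
    cluster_binding_enrichment,
    read_narrowpeak,
)
from oracles import brute_force_assign


def _tx(gene, start, end, strand="+", chrom="chr1"):
    return TranscriptRecord(f"{gene}.t", gene, chrom, strand, start, end)


class TestReadNarrowpeak:
    def test_summit_from_offset(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t100\t300\tp1\t0\t.\t5\t4\t3\t50\n")
        (peak,) = read_narrowpeak(p)
        assert peak.summit == 150

    def test_missing_summit_falls_back_to_midpoint(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t100\t300\tp1\t0\t.\t5\t4\t3\t-1\n")
        (peak,) = read_narrowpeak(p)
        assert peak.summit == 200

    def test_six_column_bed_rejected(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t300\tp1\t0\t.\n")
        with pytest.raises(ParseError):
            read_narrowpeak(p)

    def test_summit_outside_interval_rejected(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t100\t300\tp1\t0\t.\t5\t4\t3\t500\n")
        with pytest.raises(ValidationError):
            read_narrowpeak(p)


class TestAssignment:
    def test_upstream_peak_assigned_plus_strand(self):
        tx = _tx("gA", 100_000, 120_000)
        peak = Peak("p1", "chr1", 95_000, 95_200, 95_100)
        assert assign_peaks_to_genes([peak], [tx]) == {"gA": {"p1"}}

    def test_peak_beyond_upstream_boundary_not_assigned(self):
        tx = _tx("gA", 100_000, 120_000)
        peak = Peak("p1", "chr1", 89_000, 89_900, 89_400)  # ends before 90 kb
        assert assign_peaks_to_genes([peak], [tx]) == {}

    def test_boundary_touching_peak_assigned(self):
        tx = _tx("gA", 100_000, 120_000)
        peak = Peak("p1", "chr1", 89_900, 90_100, 90_000)
        assert assign_peaks_to_genes([peak], [tx]) == {"gA": {"p1"}}

    def test_minus_strand_upstream_is_higher_coordinates(self):
        tx = _tx("gB", 50_000, 70_000, strand="-")
        up = Peak("p1", "chr1", 75_000, 75_100, 75_050)
        down = Peak("p2", "chr1", 81_000, 81_100, 81_050)  # beyond 70k + 10k
        assert assign_peaks_to_genes([up, down], [tx]) == {"gB": {"p1"}}

    def test_peak_on_geneless_chromosome_unassigned(self):
        peak = Peak("p1", "chrM", 10, 200, 100)
        assert assign_peaks_to_genes([peak], [_tx("gA", 0, 5000)]) == {}

    def test_summit_only_mode_requires_summit_containment(self):
        tx = _tx("gA", 100_000, 120_000)
        straddle = Peak("p1", "chr1", 89_500, 90_500, 89_700)
        assert assign_peaks_to_genes([straddle], [tx]) == {"gA": {"p1"}}
        assert assign_peaks_to_genes([straddle], [tx], summit_only=True) == {}

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        transcripts = []
        for i in range(200):
            start = int(rng.integers(0, 5_000_000))
            length = int(rng.integers(2000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom = f"chr{int(rng.integers(1, 4))}"
            transcripts.append(_tx(f"g{i}", start, start + length, strand, chrom))
        peaks = []
        for j in range(500):
            start = int(rng.integers(0, 5_000_000))
            width = int(rng.integers(50, 2000))
            chrom = f"chr{int(rng.integers(1, 4))}"
            peaks.append(Peak(f"p{j}", chrom, start, start + width,
                              start + width // 2))
        # deliberate +/- strand 10-kb boundary cases
        transcripts += [_tx("gplus", 1_000_000, 1_010_000, "+"),
                        _tx("gminus", 2_000_000, 2_010_000, "-")]
        peaks += [
            Peak("edge1", "chr1", 989_999, 990_000 + 1, 990_000),
            Peak("edge2", "chr1", 985_000, 990_000, 987_000),
            Peak("edge3", "chr1", 2_019_999, 2_020_001, 2_020_000),
            Peak("edge4", "chr1", 2_020_000, 2_020_500, 2_020_200),
        ]
        got = assign_peaks_to_genes(peaks, transcripts)
        expected = brute_force_assign(peaks, transcripts)
        assert got == expected


class TestDynamics:
    def test_categories(self):
        genes = ["g1", "g2", "g3", "g4"]
        a = {"g1": {"p"}, "g3": {"p"}}
        b = {"g2": {"q"}, "g3": {"q"}}
        dyn = classify_dynamics(a, b, genes)
        assert dyn == {"g1": "loss", "g2": "gain", "g3": "constitutive", "g4": "none"}

    def test_categories_partition_gene_set(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(100)]
        a = {g: {"p"} for g in genes if rng.random() < 0.4}
        b = {g: {"q"} for g in genes if rng.random() < 0.4}
        dyn = classify_dynamics(a, b, genes)
        assert sorted(dyn) == sorted(genes)
        counts = {c: sum(1 for v in dyn.values() if v == c)
                  for c in ("gain", "loss", "constitutive", "none")}
        assert sum(counts.values()) == len(genes)


class TestBindingEnrichment:
    def test_percentages(self):
        membership = {f"g{i}": {1} for i in range(10)}
        membership.update({f"h{i}": {2} for i in range(10)})
        universe = set(membership)
        bound = {f"g{i}" for i in range(8)}
        table = cluster_binding_enrichment(membership, bound, universe, 2)
        assert table.loc[table.cluster == 1, "percent_bound"].item() == pytest.approx(80.0)
        assert table.loc[table.cluster == 2, "percent_bound"].item() == pytest.approx(0.0)

    def test_all_bound_gives_p_one(self):
        membership = {f"g{i}": {(i % 3) + 1} for i in range(30)}
        universe = set(membership)
        table = cluster_binding_enrichment(membership, universe, universe, 3)
        assert np.allclose(table["percent_bound"], 100.0)
        assert np.allclose(table["p_value"], 1.0)

    def test_empty_cluster_reported_missing(self):
        membership = {f"g{i}": {1} for i in range(10)}
        table = cluster_binding_enrichment(membership, set(), set(membership), 3)
        assert np.isnan(table.loc[table.cluster == 3, "percent_bound"].item())
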