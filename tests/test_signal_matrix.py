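"""Coverage tracks, window binning, normalisation and input subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from profileclust.annotations import TssAnchor
from profileclust.coverage import CoverageTrack, read_coverage
from profileclust.errors import ValidationError
from profileclust.signal_matrix import (
    SignalMatrix,
    WindowSpec,
    average_profile,
    build_signal_matrix,
    subtract_input_and_filter,
)
from oracles import per_base_window_sum


def _anchor(tss, strand="+", chrom="chr1"):
    return TssAnchor(chrom, strand, tss, frozenset({f"t{tss}{strand}"}), frozenset({f"g{tss}"}))


def _constant_track(value=1.0, total=10**6, span=10**6):
    return CoverageTrack.from_intervals(
        {"chr1": (np.array([0]), np.array([span]), np.array([value]))}, total
    )


class TestCoverageTrack:
    def test_bedgraph_values(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("# total_mapped_reads=1000000\nchr1\t0\t100\t2.0\n")
        t = read_coverage(p)
        assert t.window_sum("chr1", 0, 100) == pytest.approx(200.0)
        assert t.window_sum("chr1", 100, 200) == 0.0
        assert t.total_mapped_reads == 10**6

    def test_total_reads_argument_overrides_header(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t100\t1.0\n")
        assert read_coverage(p, total_reads=5).total_mapped_reads == 5
        with pytest.raises(ValidationError, match="total_mapped_reads"):
            read_coverage(p)

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("# total_mapped_reads=10\nchr1\t0\t100\t1.0\nchr1\t50\t150\t2.0\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_coverage(p)

    def test_read_extension_rule(self, tmp_path):
        sam = tmp_path / "r.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        t = read_coverage(sam, format="sam", fragment_extension_bp=200)
        # one + strand 50-bp read at 0-based 100, extended to 200 bp of fragment
        assert t.window_sum("chr1", 100, 300) == pytest.approx(200.0)
        assert t.window_sum("chr1", 300, 400) == 0.0
        assert t.total_mapped_reads == 1

    def test_gap_between_intervals_is_zero(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("# total_mapped_reads=10\nchr1\t0\t10\t1.0\nchr1\t20\t30\t3.0\n")
        t = read_coverage(p)
        assert t.window_sum("chr1", 10, 20) == 0.0
        assert t.window_sum("chr1", 0, 30) == pytest.approx(40.0)


class TestBuildSignalMatrix:
    def test_constant_coverage_norm_factor_one(self):
        m = build_signal_matrix(_constant_track(1.0, 10**6), [_anchor(10_000)])
        assert m.values.shape == (1, 60)
        assert np.allclose(m.values, 100.0)

    def test_per_million_scaling(self):
        m = build_signal_matrix(_constant_track(1.0, 2 * 10**6), [_anchor(10_000)])
        assert np.allclose(m.values, 50.0)

    def test_strand_flip_maps_mirror_images_to_identical_rows(self):
        tss = 50_000
        plus_track = CoverageTrack.from_intervals(
            {"chr1": (np.array([tss - 99]), np.array([tss + 1]), np.array([1.0]))}, 10**6
        )
        minus_track = CoverageTrack.from_intervals(
            {"chr1": (np.array([tss]), np.array([tss + 100]), np.array([1.0]))}, 10**6
        )
        row_plus = build_signal_matrix(plus_track, [_anchor(tss, "+")]).values[0]
        row_minus = build_signal_matrix(minus_track, [_anchor(tss, "-")]).values[0]
        assert np.allclose(row_plus, row_minus)
        # offset 0 is the TSS base itself, so the 100-bp patch straddles
        # the bin boundary: 99 bases upstream-adjacent, 1 base at the TSS
        assert row_plus[19] == pytest.approx(99.0)
        assert row_plus[20] == pytest.approx(1.0)
        assert np.flatnonzero(row_plus).tolist() == [19, 20]

    def test_matches_per_base_summation_oracle(self):
        rng = np.random.default_rng(0)
        starts = np.arange(0, 300_000, 500)
        values = rng.integers(0, 5, size=len(starts)).astype(float)
        track = CoverageTrack.from_intervals(
            {"chr1": (starts, starts + 500, values)}, 10**6
        )
        sparse = {}
        for s, v in zip(starts, values):
            if v:
                for pos in range(s, s + 500):
                    sparse[pos] = v
        for tss, strand in [(150_000, "+"), (150_037, "-")]:
            row = build_signal_matrix(track, [_anchor(tss, strand)]).values[0]
            oracle = per_base_window_sum(sparse, tss, strand, 2000, 4000, 100)
            assert np.allclose(row, oracle)

    def test_missing_chromosome_gives_zero_row(self):
        m = build_signal_matrix(
            _constant_track(), [_anchor(10_000), _anchor(10_000, chrom="chrUn")]
        )
        assert np.allclose(m.values[1], 0.0)
        assert not np.allclose(m.values[0], 0.0)

    def test_chromosome_edge_window_is_zero_padded(self):
        track = CoverageTrack.from_intervals(
            {"chr1": (np.array([0]), np.array([3000]), np.array([1.0]))}, 10**6
        )
        row = build_signal_matrix(track, [_anchor(500)]).values[0]
        # bins beyond the covered span contribute nothing on either side
        assert row[0] == 0.0 and row[-1] == 0.0 and row[20] == pytest.approx(100.0)

    def test_bin_conservation_against_single_bin_window(self):
        rng = np.random.default_rng(1)
        starts = np.arange(0, 200_000, 100)
        values = rng.random(len(starts)) * 3
        track = CoverageTrack.from_intervals({"chr1": (starts, starts + 100, values)}, 10**6)
        fine = build_signal_matrix(track, [_anchor(100_000)], WindowSpec(2000, 4000, 100))
        coarse = build_signal_matrix(track, [_anchor(100_000)], WindowSpec(2000, 4000, 6000))
        assert fine.values.sum() == pytest.approx(coarse.values.sum())


@settings(max_examples=30, deadline=None)
@given(st.floats(min_value=0.1, max_value=50), st.integers(min_value=1, max_value=10))
def test_per_million_invariance(value, scale):
    """Scaling coverage and library size together leaves the matrix unchanged."""
    base = build_signal_matrix(_constant_track(value, 10**6), [_anchor(10_000)])
    scaled = build_signal_matrix(
        _constant_track(value * scale, scale * 10**6), [_anchor(10_000)]
    )
    assert np.allclose(base.values, scaled.values)


class TestSubtractAndAverage:
    def _matrix(self, values, label="s", subtracted=False):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        anchors = [_anchor(10_000 + 100_000 * i) for i in range(values.shape[0])]
        return SignalMatrix(anchors, values, label, WindowSpec(),
                            input_subtracted=subtracted)

    def test_identical_sample_and_input_discards_everything(self):
        m = self._matrix(np.ones((3, 60)))
        out = subtract_input_and_filter(m, self._matrix(np.ones((3, 60)), "i"))
        assert len(out) == 0 and out.input_subtracted

    def test_double_input_retains_input_values(self):
        inp = self._matrix(np.full((2, 60), 0.5), "i")
        out = subtract_input_and_filter(self._matrix(np.full((2, 60), 1.0)), inp)
        assert len(out) == 2
        assert np.allclose(out.values, 0.5)

    def test_tiny_positive_row_sum_is_retained(self):
        sample = np.zeros((1, 60))
        sample[0, 0] = 0.001
        out = subtract_input_and_filter(self._matrix(sample), self._matrix(np.zeros((1, 60)), "i"))
        assert len(out) == 1

    def test_anchor_mismatch_rejected(self):
        a = self._matrix(np.ones((2, 60)))
        b = self._matrix(np.ones((3, 60)), "i")
        with pytest.raises(ValidationError):
            subtract_input_and_filter(a, b)

    def test_clamp_negative_floors_bins(self):
        sample = np.full((1, 60), 1.0)
        sample[0, 0] = 0.0
        inp = np.full((1, 60), 0.5)
        out = subtract_input_and_filter(
            self._matrix(sample), self._matrix(inp, "i"), clamp_negative=True
        )
        assert out.values.min() == 0.0

    def test_average_profile_identity_and_symmetry(self):
        row = np.arange(60, dtype=float)
        assert np.allclose(average_profile(self._matrix(row, subtracted=True)), row)
        sym = self._matrix(np.vstack([row, -row]), subtracted=True)
        assert np.allclose(average_profile(sym), 0.0)

    def test_average_profile_matches_column_means(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(100, 60))
        m = self._matrix(values, subtracted=True)
        oracle = [sum(values[:, j]) / 100 for j in range(60)]
        assert np.allclose(average_profile(m), oracle)

    def test_empty_matrix_rejected(self):
        m = SignalMatrix([], np.empty((0, 60)), "s", WindowSpec())
        with pytest.raises(ValidationError):
            average_profile(m)
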