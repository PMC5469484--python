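"""Genome-wide coverage tracks and their readers.

A :class:`CoverageTrack` stores per-chromosome piecewise-constant coverage
together with the library size used for per-million normalisation.  Bin sums
are evaluated through a prefix integral, so window extraction is O(bins)
regardless of track size.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["CoverageTrack", "read_coverage"]

_TOTAL_RE = re.compile(r"total_mapped_reads\s*=\s*(\d+)")


@dataclass
class CoverageTrack:
    """Piecewise-constant non-negative coverage over 0-based half-open intervals."""

    label: str
    total_mapped_reads: int
    _bp: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _val: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValidationError("total_mapped_reads must be positive")

    @classmethod
    def from_intervals(
        cls,
        intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_mapped_reads: int,
        label: str = "",
    ) -> "CoverageTrack":
        """Build a track from per-chromosome (starts, ends, values) arrays.

        Intervals are sorted by start; overlapping intervals are rejected.
        Gaps are implicit zeros; positions outside the recorded span are zero.
        """
        track = cls(label=label, total_mapped_reads=total_mapped_reads)
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if starts.size == 0:
                continue
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: empty or inverted interval")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping coverage intervals")
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: negative coverage value")
            # breakpoints include zero-valued gaps so lookup is uniform
            bp = np.unique(np.concatenate([starts, ends]))
            idx = np.searchsorted(starts, bp[:-1], side="right") - 1
            inside = (idx >= 0) & (bp[:-1] < ends[np.clip(idx, 0, None)])
            seg = np.where(inside, values[np.clip(idx, 0, None)], 0.0)
            cum = np.concatenate([[0.0], np.cumsum(seg * np.diff(bp))])
            track._bp[chrom] = bp
            track._val[chrom] = seg
            track._cum[chrom] = cum
        return track

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._bp)

    def has_chromosome(self, chrom: str) -> bool:
        return chrom in self._bp

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of coverage over [span_start, x) for each x (vectorised)."""
        bp = self._bp[chrom]
        x = np.clip(np.asarray(positions, dtype=np.int64), bp[0], bp[-1])
        i = np.clip(np.searchsorted(bp, x, side="right") - 1, 0, len(self._val[chrom]) - 1)
        return self._cum[chrom][i] + self._val[chrom][i] * (x - bp[i])

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total coverage mass over [start, end); 0 for unknown chromosomes."""
        if chrom not in self._bp:
            return 0.0
        f = self.integral(chrom, np.array([start, end]))
        return float(f[1] - f[0])


def _read_bedgraph(path: Path, total_reads: int | None, label: str) -> CoverageTrack:
    import pandas as pd

    header_total = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith(("#", "track", "browser")) or not stripped:
                m = _TOTAL_RE.search(stripped)
                if m:
                    header_total = int(m.group(1))
                skip += 1
                continue
            break
    try:
        df = pd.read_csv(
            path, sep=r"\s+", skiprows=skip, header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed bedGraph ({exc})") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: malformed bedGraph (missing fields)")
    total = total_reads if total_reads is not None else header_total
    if total is None:
        raise ValidationError(
            "bedGraph input needs total_mapped_reads, either as an argument or a "
            "'# total_mapped_reads=N' header line"
        )
    intervals = {
        str(chrom): (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(),
        )
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return CoverageTrack.from_intervals(intervals, total, label=label)


def _read_alignments(path: Path, fragment_extension_bp: int, total_reads: int | None,
                     label: str) -> CoverageTrack:
    # streamed sequentially, so no index is required and plain-text SAM works
    import pysam

    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    n_reads = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n_reads += 1
            s, e = read.reference_start, read.reference_end
            if fragment_extension_bp > 0:
                if read.is_reverse:
                    s = max(0, e - fragment_extension_bp)
                else:
                    e = s + fragment_extension_bp
            chrom = read.reference_name
            starts.setdefault(chrom, []).append(s)
            ends.setdefault(chrom, []).append(e)
    if n_reads == 0:
        raise ValidationError(f"{path}: no mapped reads")
    intervals = {}
    for chrom in starts:
        s = np.array(starts[chrom], dtype=np.int64)
        e = np.array(ends[chrom], dtype=np.int64)
        bp = np.unique(np.concatenate([s, e]))
        depth = np.zeros(len(bp), dtype=np.int64)
        np.add.at(depth, np.searchsorted(bp, s), 1)
        np.subtract.at(depth, np.searchsorted(bp, e), 1)
        depth = np.cumsum(depth)[:-1]
        intervals[chrom] = (bp[:-1], bp[1:], depth.astype(float))
    total = total_reads if total_reads is not None else n_reads
    return CoverageTrack.from_intervals(intervals, total, label=label)


def read_coverage(
    path: str | Path,
    format: str = "bedGraph",
    fragment_extension_bp: int = 0,
    total_reads: int | None = None,
    label: str | None = None,
) -> CoverageTrack:
    """Read a coverage track from bedGraph or from single-end alignments.

    For alignments, each read is extended 3'-ward to ``fragment_extension_bp``
    (the sequenced fragment size) before pile-up; the library size is the
    mapped-read count.  For bedGraph the library size is a side channel:
    pass ``total_reads`` or embed ``# total_mapped_reads=N`` in the header.
    """
    path = Path(path)
    if fragment_extension_bp < 0:
        raise ValidationError("fragment_extension_bp must be >= 0")
    fmt = format.lower()
    if label is None:
        label = path.stem
    if fmt == "bedgraph":
        return _read_bedgraph(path, total_reads, label)
    if fmt in {"bam", "sam"}:
        return _read_alignments(path, fragment_extension_bp, total_reads, label)
    raise ValidationError(f"unknown coverage format {format!r}")
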