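"""TF peak parsing, peak-to-gene assignment and binding dynamics.

A peak is assigned to a gene when its interval overlaps the gene's eligible
region: the transcribed region plus 10 kb upstream of the TSS (strand
aware, so "upstream" means lower coordinates for '+' genes and higher
coordinates for '-' genes).  Assignment uses the full transcript set;
reporting is then restricted to whatever gene universe the caller analyses.
Comparing assignments between two conditions classifies each gene as
gaining, losing, constitutively having or never having a peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotations import TranscriptRecord
from .cluster_comparison import GeneClusterMembership
from .errors import ParseError, ValidationError
from . import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "BindingDynamics",
    "read_narrowpeak",
    "assign_peaks_to_genes",
    "classify_dynamics",
    "cluster_binding_enrichment",
]

BindingDynamics = dict[str, str]  # gene -> gain | loss | constitutive | none


@dataclass(frozen=True)
class Peak:
    """A called TF peak with its summit (absolute genomic position)."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.summit < self.end):
            raise ValidationError(
                f"{self.peak_id}: summit {self.summit} outside [{self.start}, {self.end})"
            )


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak file (10 columns; column 10 = summit offset).

    A summit offset of -1 (unknown) falls back to the interval midpoint,
    which is logged.
    """
    path = Path(path)
    peaks: list[Peak] = []
    n_fallback = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            offset = int(fields[9])
            if offset == -1:
                summit = (start + end) // 2
                n_fallback += 1
            else:
                summit = start + offset
            if not (start <= summit < end):
                raise ValidationError(f"{path}:{lineno}: summit outside the peak interval")
            peaks.append(Peak(name or f"peak_{lineno}", chrom, start, end, summit,
                              float(fields[6])))
    if n_fallback:
        logger.info("%s: %d peak(s) without a summit; midpoint used", path, n_fallback)
    return peaks


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    transcripts: Sequence[TranscriptRecord],
    upstream_bp: int = 10_000,
    summit_only: bool = False,
) -> dict[str, set[str]]:
    """Map gene -> set of overlapping peak ids.

    The eligible region of a '+' transcript is [start - upstream_bp, end),
    of a '-' transcript [start, end + upstream_bp); a peak is assigned when
    its interval intersects the eligible region of any transcript of the
    gene (``summit_only`` instead requires the summit to fall inside).
    """
    if upstream_bp < 0:
        raise ValidationError("upstream_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        if t.strand == "+":
            lo, hi = max(0, t.start - upstream_bp), t.end
        else:
            lo, hi = t.start, t.end + upstream_bp
        trees.setdefault(t.chrom, IntervalTree()).addi(lo, hi, t.gene_id)
    assignment: dict[str, set[str]] = {}
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        hits = tree.at(p.summit) if summit_only else tree.overlap(p.start, p.end)
        for iv in hits:
            assignment.setdefault(iv.data, set()).add(p.peak_id)
    return assignment


def classify_dynamics(
    assign_a: Mapping[str, set[str]],
    assign_b: Mapping[str, set[str]],
    genes: Iterable[str],
) -> BindingDynamics:
    """Per-gene binding dynamics between condition A and condition B."""
    dynamics: BindingDynamics = {}
    for g in genes:
        in_a = bool(assign_a.get(g))
        in_b = bool(assign_b.get(g))
        if in_a and in_b:
            dynamics[g] = "constitutive"
        elif in_b:
            dynamics[g] = "gain"
        elif in_a:
            dynamics[g] = "loss"
        else:
            dynamics[g] = "none"
    return dynamics


def cluster_binding_enrichment(
    membership: GeneClusterMembership,
    bound: Iterable[str],
    universe: Iterable[str],
    k: int,
) -> pd.DataFrame:
    """Percentage of bound genes per cluster with a two-sided Fisher test.

    Each cluster is tested against all other genes of the universe
    (2x2: bound/unbound x in-cluster/out-of-cluster).  Empty clusters get
    NaN percentage and p-value.
    """
    universe = set(universe)
    bound = set(bound)
    if not bound <= universe:
        raise ValidationError("bound genes must be a subset of the universe")
    rows = []
    n_bound_total = len(bound)
    for c in range(1, k + 1):
        in_c = {g for g in universe if c in membership.get(g, ())}
        n_c = len(in_c)
        if n_c == 0:
            rows.append((c, 0, 0, float("nan"), float("nan")))
            continue
        a = len(bound & in_c)
        table = [[a, n_c - a], [n_bound_total - a, len(universe) - n_c - (n_bound_total - a)]]
        rows.append((c, n_c, a, 100.0 * a / n_c, stats.fisher_exact_two_sided(table)))
    return pd.DataFrame(
        rows, columns=["cluster", "n_genes", "n_bound", "percent_bound", "p_value"]
    )
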