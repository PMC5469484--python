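"""Gene-model ingestion and derivation of the unique TSS set.

Every downstream signal window is anchored on a transcription start site
(TSS): the first *transcribed* base of a transcript, which is the interval
start on the plus strand and the last base of the half-open interval on the
minus strand.  Transcripts are deduplicated on coordinates, filtered by
length (short genes cannot carry a -2 kb/+4 kb profile without running into
their neighbours' signal), and collapsed to unique ``(chrom, strand, tss)``
anchors, each remembering the transcripts and genes it represents.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError

__all__ = [
    "TranscriptRecord",
    "TssAnchor",
    "read_gene_models",
    "deduplicate_transcripts",
    "filter_by_length",
    "collapse_tss",
    "write_anchor_bed",
    "read_anchor_bed",
]

_STRANDS = {"+", "-"}
# tolerate the typographic minus occasionally found in exported tables
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript interval of a gene model."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) for {self.transcript_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """First transcribed base: start on '+', end - 1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class TssAnchor:
    """A unique (chrom, strand, tss) position with its transcript/gene sets."""

    chrom: str
    strand: str
    tss: int
    transcript_ids: frozenset[str]
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")
        if self.tss < 0:
            raise ValidationError("TSS must be non-negative")
        if not self.transcript_ids:
            raise ValidationError("anchor must represent at least one transcript")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.tss}:{self.strand}"


def _split_name(name: str) -> tuple[str, str]:
    """BED12 name convention: ``gene|transcript``; bare names serve as both."""
    if "|" in name:
        gene, tx = name.split("|", 1)
        return gene, tx
    return name, name


def read_gene_models(path: str | Path, format: str = "refFlat") -> list[TranscriptRecord]:
    """Read transcript models from a refFlat (UCSC 11-column) or BED12 file.

    Duplicate transcript identifiers are allowed across chromosomes
    (common for haplotype contigs); duplicates on the same chromosome
    trigger a warning but are kept.
    """
    fmt = format.lower().replace("-", "")
    if fmt not in {"refflat", "bed12"}:
        raise ValidationError(f"unknown gene-model format {format!r}")
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "bed12":
                    if len(fields) != 12:
                        raise ParseError(
                            f"{path}:{lineno}: expected 12 BED columns, got {len(fields)}"
                        )
                    chrom, start, end, name, _score, strand = fields[:6]
                    gene_id, tx_id = _split_name(name)
                else:
                    if len(fields) < 11:
                        raise ParseError(
                            f"{path}:{lineno}: expected 11 refFlat columns, got {len(fields)}"
                        )
                    gene_id, tx_id, chrom, strand, start, end = fields[:6]
                strand = _STRAND_ALIASES.get(strand)
                if strand is None:
                    raise ValidationError(f"{path}:{lineno}: unknown strand symbol")
                rec = TranscriptRecord(tx_id, gene_id, chrom, strand, int(start), int(end))
            except (ValueError, ValidationError) as exc:
                if isinstance(exc, (ParseError, ValidationError)):
                    raise
                raise ParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if tx_id in seen and chrom in seen[tx_id]:
                warnings.warn(
                    f"duplicate transcript id {tx_id!r} on {chrom} ({path}:{lineno})",
                    stacklevel=2,
                )
            seen.setdefault(tx_id, set()).add(chrom)
            records.append(rec)
    return records


def deduplicate_transcripts(transcripts: Iterable[TranscriptRecord]) -> list[TranscriptRecord]:
    """Keep the first transcript per (chrom, strand, start, end); preserve order."""
    out: list[TranscriptRecord] = []
    seen: set[tuple[str, str, int, int]] = set()
    for t in transcripts:
        key = (t.chrom, t.strand, t.start, t.end)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def filter_by_length(
    transcripts: Sequence[TranscriptRecord], min_length: int = 4000
) -> list[TranscriptRecord]:
    """Retain transcripts at least ``min_length`` bp long (inclusive)."""
    if min_length < 1:
        raise ValidationError("min_length must be >= 1")
    return [t for t in transcripts if t.length >= min_length]


def collapse_tss(transcripts: Sequence[TranscriptRecord]) -> list[TssAnchor]:
    """Collapse transcripts to unique (chrom, strand, tss) anchors.

    Transcript and gene identifier sets are unioned per anchor; a gene whose
    transcripts start at distinct positions yields multiple anchors.  Output
    is sorted by (chrom, tss, strand) for determinism.
    """
    acc: dict[tuple[str, str, int], tuple[set[str], set[str]]] = {}
    for t in transcripts:
        key = (t.chrom, t.strand, t.tss)
        txs, genes = acc.setdefault(key, (set(), set()))
        txs.add(t.transcript_id)
        genes.add(t.gene_id)
    anchors = [
        TssAnchor(chrom, strand, tss, frozenset(txs), frozenset(genes))
        for (chrom, strand, tss), (txs, genes) in acc.items()
    ]
    anchors.sort(key=lambda a: (a.chrom, a.tss, a.strand))
    return anchors


def write_anchor_bed(anchors: Iterable[TssAnchor], path: str | Path) -> None:
    """Write anchors as BED6; the name column encodes ``genes|transcripts``."""
    with open(path, "w") as fh:
        for a in anchors:
            name = ",".join(sorted(a.gene_ids)) + "|" + ",".join(sorted(a.transcript_ids))
            fh.write(f"{a.chrom}\t{a.tss}\t{a.tss + 1}\t{name}\t0\t{a.strand}\n")


def read_anchor_bed(path: str | Path) -> list[TssAnchor]:
    """Inverse of :func:`write_anchor_bed`."""
    anchors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, _end, name, _score, strand = fields[:6]
            genes, txs = name.split("|", 1)
            anchors.append(
                TssAnchor(
                    chrom,
                    _STRAND_ALIASES.get(strand, strand),
                    int(start),
                    frozenset(txs.split(",")),
                    frozenset(genes.split(",")),
                )
            )
    return anchors
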