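"""E-box motif scanning under peak summits.

MyoD binds the degenerate E-box CANNTG; the variant CAGCTG (a G/C central
dinucleotide) confers preferential MyoD affinity and is flagged separately.
Both pattern classes are their own reverse complements, so a forward-strand
scan of the degenerate class is strand-complete.  Scanning happens inside a
short window (30 bp by default) centred on each peak summit, where the
functional binding site is expected to sit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pyfaidx import Fasta

from .errors import ValidationError
from .peak_integration import Peak

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "IUPAC",
    "extract_summit_window",
    "scan_ebox",
    "scan_peaks",
    "genes_with_motif",
]

# IUPAC degenerate nucleotide codes; an 'N' in the *sequence* matches nothing.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

PREFERRED_EBOX = "CAGCTG"


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    pattern: str
    window_offset: int
    matched_seq: str
    is_preferred: bool


def _matches(word: str, pattern: str) -> bool:
    return len(word) == len(pattern) and all(
        base in IUPAC[sym] for base, sym in zip(word, pattern)
    )


def extract_summit_window(
    genome: Fasta | str | Path, peak: Peak, window_bp: int = 30
) -> str:
    """Uppercase sequence of [summit - w/2, summit + w/2), edge-truncated.

    Windows running past a chromosome end are truncated (and logged) rather
    than padded, so the returned string can be shorter than ``window_bp``.
    """
    if window_bp < 1:
        raise ValidationError("window_bp must be positive")
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    if peak.chrom not in genome:
        raise LookupError(f"chromosome {peak.chrom!r} absent from FASTA")
    chrom_len = len(genome[peak.chrom])
    half = window_bp // 2
    lo = peak.summit - half
    hi = peak.summit + (window_bp - half)
    lo_c, hi_c = max(0, lo), min(chrom_len, hi)
    if (lo_c, hi_c) != (lo, hi):
        logger.info("%s: summit window truncated to [%d, %d)", peak.peak_id, lo_c, hi_c)
    return str(genome[peak.chrom][lo_c:hi_c]).upper()


def scan_ebox(
    sequence: str,
    patterns: Sequence[str] = ("CANNTG", PREFERRED_EBOX),
    peak_id: str = "",
) -> list[MotifHit]:
    """All offsets where a full pattern occurrence fits inside ``sequence``.

    One hit is emitted per offset matching any pattern; a hit is flagged
    preferred when the 6-mer also matches CAGCTG.  The degenerate E-box
    class is reverse-complement closed, so only the forward strand is
    scanned.
    """
    seq = sequence.upper()
    if any(b not in "ACGTN" for b in seq):
        raise ValidationError("sequence must be over {A, C, G, T, N}")
    for p in patterns:
        if any(s not in IUPAC for s in p.upper()):
            raise ValidationError(f"invalid IUPAC pattern {p!r}")
    patterns = [p.upper() for p in patterns]
    check_preferred = PREFERRED_EBOX in patterns
    hits: list[MotifHit] = []
    width = len(patterns[0])
    if any(len(p) != width for p in patterns):
        raise ValidationError("all patterns must share one length")
    for off in range(len(seq) - width + 1):
        word = seq[off : off + width]
        matched = [p for p in patterns if _matches(word, p)]
        if matched:
            preferred = check_preferred and _matches(word, PREFERRED_EBOX)
            hits.append(MotifHit(peak_id, matched[0], off, word, preferred))
    return hits


def scan_peaks(
    genome: Fasta | str | Path,
    peaks: Iterable[Peak],
    window_bp: int = 30,
    patterns: Sequence[str] = ("CANNTG", PREFERRED_EBOX),
) -> list[MotifHit]:
    """Extract each peak's summit window and scan it; hits carry the peak id."""
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    hits: list[MotifHit] = []
    for p in peaks:
        window = extract_summit_window(genome, p, window_bp)
        hits.extend(scan_ebox(window, patterns, peak_id=p.peak_id))
    return hits


def genes_with_motif(
    assignments: Mapping[str, set[str]], hits: Iterable[MotifHit]
) -> dict[str, dict[str, bool]]:
    """Per-gene motif flags: any assigned peak with a hit / a preferred hit."""
    with_hit = {h.peak_id for h in hits}
    with_preferred = {h.peak_id for h in hits if h.is_preferred}
    return {
        gene: {
            "has_ebox": bool(peak_ids & with_hit),
            "has_preferred": bool(peak_ids & with_preferred),
        }
        for gene, peak_ids in assignments.items()
    }
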