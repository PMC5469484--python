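"""Independent brute-force / rational-arithmetic oracles used by the tests.

Everything here is deliberately naive and slow: rational hypergeometric
enumeration for the exact tests, a per-base summation oracle for signal
binning, an all-offsets/both-strands scanner for motifs, and an all-pairs
interval check for peak assignment.  None of it shares code with the
package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

REL_TOL = Fraction(1, 10**7)  # comparison slack of the two-sided Fisher criterion


def hypergeom_tail_fraction(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), as an exact rational."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def fisher_two_sided_fraction(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by rational enumeration over all same-margin tables."""
    N = a + b + c + d
    r1, c1 = a + b, a + c
    total = comb(N, c1)
    support = range(max(0, c1 - (N - r1)), min(r1, c1) + 1)
    probs = {i: Fraction(comb(r1, i) * comb(N - r1, c1 - i), total) for i in support}
    threshold = probs[a] * (1 + REL_TOL)
    return min(Fraction(1), sum(p for p in probs.values() if p <= threshold))


@lru_cache(maxsize=None)
def _mw_count(nx: int, ny: int, u: int) -> int:
    """Number of rank interleavings with U(x) = u, U = #pairs where x > y."""
    if u < 0:
        return 0
    if nx == 0 or ny == 0:
        return 1 if u == 0 else 0
    return _mw_count(nx - 1, ny, u - ny) + _mw_count(nx, ny - 1, u)


def mann_whitney_two_sided_fraction(nx: int, ny: int, u: int) -> Fraction:
    """Exact two-sided p for an observed U, doubling the smaller tail."""
    total = comb(nx + ny, nx)
    dist = [_mw_count(nx, ny, v) for v in range(nx * ny + 1)]
    cdf = Fraction(sum(dist[: u + 1]), total)
    sf = Fraction(sum(dist[u:]), total)
    return min(Fraction(1), 2 * min(cdf, sf))


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def naive_scan_offsets(seq: str, pattern: str) -> set[int]:
    """Offsets where pattern or its reverse complement matches, both strands."""
    seq = seq.upper()
    out = set()
    for pat in {pattern.upper(), revcomp(pattern.upper())}:
        w = len(pat)
        for off in range(len(seq) - w + 1):
            word = seq[off : off + w]
            if all(b in _IUPAC[p] for b, p in zip(word, pat)):
                out.add(off)
    return out


def brute_force_assign(peaks, transcripts, upstream_bp: int = 10_000) -> dict[str, set[str]]:
    """All-pairs peak x transcript interval intersection check."""
    out: dict[str, set[str]] = {}
    for p in peaks:
        for t in transcripts:
            if t.chrom != p.chrom:
                continue
            if t.strand == "+":
                lo, hi = max(0, t.start - upstream_bp), t.end
            else:
                lo, hi = t.start, t.end + upstream_bp
            if p.start < hi and p.end > lo:
                out.setdefault(t.gene_id, set()).add(p.peak_id)
    return out


def per_base_window_sum(coverage: dict[int, float], tss: int, strand: str,
                        upstream: int, downstream: int, bin_bp: int) -> list[float]:
    """Per-base summation of a sparse {position: value} coverage map."""
    n_bins = (upstream + downstream) // bin_bp
    sums = [0.0] * n_bins
    for b in range(n_bins):
        for o in range(-upstream + b * bin_bp, -upstream + (b + 1) * bin_bp):
            pos = tss + o if strand == "+" else tss - o
            sums[b] += coverage.get(pos, 0.0)
    return sums
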