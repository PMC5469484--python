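"""Exact and adjusted statistics used across the pipeline.

Thin, validated decision layers over scipy's distributions: the two-sided
Fisher test uses the point-probability criterion (sum all tables with the
observed margins whose probability does not exceed the observed table's,
with a small relative tolerance guarding floating-point ties), the
Mann-Whitney test switches between the exact permutation distribution and
the tie/continuity-corrected normal approximation at a combined sample size
of 20, and the hypergeometric tail is the upper tail P(X >= k).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "hypergeometric_tail",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "bh_adjust",
    "gene_set_enrichment",
    "read_gmt",
]


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if N <= 0:
        raise ValidationError("population size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("require 0 <= K, n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValidationError("require 0 <= k <= min(K, n)")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_two_sided(table: Sequence[Sequence[int]], rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher's exact test on a 2x2 table, point-probability criterion."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be non-negative")
    N = a + b + c + d
    if N == 0:
        raise ValidationError("table must have at least one observation")
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (N - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, N, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(1.0, p)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> tuple[float, float]:
    """Mann-Whitney U (statistic of ``x``) with a two-sided p-value.

    Exact permutation distribution when the combined sample size is at most
    ``exact_limit`` and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= exact_limit and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(1.0, res.pvalue))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def gene_set_enrichment(
    query: Iterable[str],
    reference_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided Fisher enrichment of ``query`` in each reference set, BH-adjusted.

    Every set must be contained in ``universe``.  Returns one row per
    reference set with the overlap count, raw and adjusted p-values, and a
    significance flag at ``alpha`` (adjusted p <= alpha).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = set(query)
    if not query <= universe:
        raise ValidationError("query set is not a subset of the universe")
    names, ks, ps, sizes = [], [], [], []
    N = len(universe)
    for name, ref in reference_sets.items():
        ref = set(ref)
        if not ref <= universe:
            raise ValidationError(f"reference set {name!r} is not a subset of the universe")
        k = len(query & ref)
        table = [
            [k, len(query) - k],
            [len(ref) - k, N - len(query) - len(ref) + k],
        ]
        names.append(name)
        ks.append(k)
        sizes.append(len(ref))
        ps.append(fisher_exact_two_sided(table))
    adj = bh_adjust(ps) if ps else np.array([])
    return pd.DataFrame(
        {
            "set_name": names,
            "set_size": sizes,
            "overlap": ks,
            "p_value": ps,
            "p_adjusted": adj,
            "significant": adj <= alpha if len(adj) else [],
        }
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets
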