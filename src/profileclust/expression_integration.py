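"""Expression tables, fold-change calls and the integrated gene funnel.

Differential expression between the two conditions uses a single-replicate
max/min fold change with a pseudocount (FC = max(a+e, b+e)/min(a+e, b+e),
e = 1 FPKM by default) and an inclusive threshold FC >= 2.  The integration
step joins every evidence layer per gene and reports the nested funnel:

    stable cluster-1 core  ->  TF-binding gain  ->  differential
    ->  down-regulated  ->  preferred E-box under the gained summit

whose final members are the candidate directly repressed TF targets.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cluster_comparison import GeneClusterMembership
from .errors import ValidationError
from . import stats

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "call_differential",
    "cluster_expression_compare",
    "integrate",
]


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV of gene_id, FPKM condition A, FPKM condition B."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected >= 3 columns (gene, fpkm_a, fpkm_b)")
    df = df.iloc[:, :3].copy()
    df.columns = ["gene_id", "fpkm_a", "fpkm_b"]
    for col in ("fpkm_a", "fpkm_b"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if df[col].isna().any():
            raise ValidationError(f"{path}: missing FPKM values in {col}")
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative FPKM values in {col}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5]
        raise ValidationError(f"{path}: duplicate gene ids (e.g. {list(dups)})")
    return df


def call_differential(
    records: pd.DataFrame, fc_threshold: float = 2.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Annotate fold change, signed log2 FC, direction and the DE flag.

    FC is symmetric (max/min with pseudocount, so FC >= 1 always); a gene is
    differential when FC >= ``fc_threshold`` (inclusive), with direction up
    when condition B exceeds A, down when below, and "flat" otherwise.
    Both-zero FPKM with pseudocount 0 yields FC = 1 (flat) rather than 0/0.
    """
    if fc_threshold < 1:
        raise ValidationError("fc_threshold must be >= 1")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    df = records.copy()
    a = df["fpkm_a"].to_numpy(dtype=float) + pseudocount
    b = df["fpkm_b"].to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where((a == 0) & (b == 0), 1.0, np.maximum(a, b) / np.minimum(a, b))
        log2fc = np.where((a == 0) | (b == 0), np.nan, np.log2(b) - np.log2(a))
    is_de = fc >= fc_threshold
    direction = np.where(
        is_de & (b > a), "up", np.where(is_de & (b < a), "down", "flat")
    )
    df["fold_change"] = fc
    df["log2_fc"] = log2fc
    df["direction"] = direction
    df["is_de"] = is_de
    return df


def cluster_expression_compare(
    membership: GeneClusterMembership,
    expression: pd.DataFrame,
    cluster_a: int,
    cluster_b: int,
    condition: str = "a",
) -> tuple[float, float]:
    """Mann-Whitney comparison of FPKM between two clusters' gene sets.

    Genes sitting in both clusters contribute to both samples (logged).
    """
    col = {"a": "fpkm_a", "b": "fpkm_b"}[condition]
    fpkm = expression.set_index("gene_id")[col]
    genes_a = [g for g, cl in membership.items() if cluster_a in cl and g in fpkm.index]
    genes_b = [g for g, cl in membership.items() if cluster_b in cl and g in fpkm.index]
    if not genes_a or not genes_b:
        raise ValidationError("both clusters must have expressed member genes")
    shared = set(genes_a) & set(genes_b)
    if shared:
        logger.info("%d gene(s) contribute to both clusters", len(shared))
    return stats.mann_whitney_u(fpkm.loc[genes_a].to_numpy(), fpkm.loc[genes_b].to_numpy())


def integrate(
    memberships: Mapping[str, GeneClusterMembership],
    stable_core: Iterable[str],
    dynamics: Mapping[str, str],
    motif_flags: Mapping[str, Mapping[str, bool]],
    expression: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Full outer join of all evidence layers plus the funnel summary.

    ``memberships`` is keyed by layer name (e.g. ``"H3K4me2_undiff"``).
    Genes absent from the expression table are kept with missing expression
    and excluded from differential counts.  The funnel counts are monotone
    non-increasing by construction.
    """
    stable_core = set(stable_core)
    expr = expression.set_index("gene_id")
    required = {"fold_change", "direction", "is_de"}
    if not required <= set(expr.columns):
        raise ValidationError("expression table must be passed through call_differential")
    genes = sorted(
        set().union(*(m.keys() for m in memberships.values()), stable_core,
                    dynamics.keys(), motif_flags.keys(), expr.index)
    )
    rows = []
    for g in genes:
        row: dict = {"gene_id": g}
        for layer, m in memberships.items():
            labels = sorted(m.get(g, ()))
            row[f"clusters_{layer}"] = ",".join(map(str, labels)) if labels else ""
        row["in_stable_core"] = g in stable_core
        row["binding_dynamics"] = dynamics.get(g, "none")
        flags = motif_flags.get(g, {})
        row["has_ebox"] = bool(flags.get("has_ebox", False))
        row["has_preferred"] = bool(flags.get("has_preferred", False))
        if g in expr.index:
            row["fpkm_a"] = float(expr.at[g, "fpkm_a"])
            row["fpkm_b"] = float(expr.at[g, "fpkm_b"])
            row["fold_change"] = float(expr.at[g, "fold_change"])
            row["direction"] = expr.at[g, "direction"]
            row["is_de"] = bool(expr.at[g, "is_de"])
        else:
            row.update(fpkm_a=np.nan, fpkm_b=np.nan, fold_change=np.nan,
                       direction="missing", is_de=False)
        rows.append(row)
    table = pd.DataFrame(rows)

    gain = {g for g in stable_core if dynamics.get(g) == "gain"}
    expressed = set(expr.index)
    de = {g for g in gain if g in expressed and bool(expr.at[g, "is_de"])}
    down = {g for g in de if expr.at[g, "direction"] == "down"}
    final = {g for g in down if motif_flags.get(g, {}).get("has_preferred", False)}
    funnel = {
        "stable_core": len(stable_core),
        "gain": len(gain),
        "gain_de": len(de),
        "gain_de_down": len(down),
        "gain_de_down_preferred": len(final),
        "final_genes": sorted(final),
    }
    return table, funnel
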