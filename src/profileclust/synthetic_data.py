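"""Self-contained synthetic dataset with serialised ground truth.

The generator emulates the statistical structure of a two-condition
chromatin study of myogenic differentiation: two histone marks profiled
around TSS plus a TF (MyoD-like) peak set, a matched input track per
condition, a genome, gene models and an FPKM table.  Six TSS-profile
archetypes drive the coverage:

    1 gene-body plateau      (high signal downstream of the TSS)
    2 bimodal TSS            (peaks flanking the TSS)
    3 narrow TSS             (single sharp peak just downstream)
    4 upstream peak          (enrichment before the TSS)
    5 low broad dome         (weak but real signal over the whole region)
    6 very low uniform       (barely above background; the class the
                              input-subtraction filter bites into)

A configurable fraction of archetype-1 genes keeps its profile in the
second condition (the rest are reassigned), TF peaks are gained upon
differentiation, preferred E-boxes (CAGCTG) are written into the genome
under a fraction of gained summits, and a planted "repressed target" gene
subset is strongly down-regulated.  Every planted fact is serialised to
``truth.json``; downstream recovery tests read only that file.

Read depths are roughly 1000x below a real ChIP-seq library, which keeps a
full dataset generation in seconds; per-bin counts are Poisson.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from pyfaidx import Fasta, Faidx

from .errors import GenerationError, ValidationError
from .signal_matrix import WindowSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "SyntheticDataset",
    "archetype_shapes",
    "generate_genome_and_annotation",
    "simulate_coverage",
    "simulate_peaks_motifs",
    "simulate_expression",
    "simulate_dataset",
    "load_truth",
]

MARKS = ("H3K4me2", "H3K4me3")
CONDITIONS = ("undiff", "diff")

ARCHETYPE_NAMES = {
    1: "gene_body_plateau",
    2: "bimodal_tss",
    3: "narrow_tss",
    4: "upstream_peak",
    5: "low_broad_dome",
    6: "very_low_uniform",
}


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults define the reference study conditions."""

    n_genes: int = 600
    n_chroms: int = 2
    chrom_length: int = 7_000_000
    short_fraction: float = 0.10  # genes below the 4-kb analysis filter
    intergenic_gap: int = 13_000  # keeps 10-kb upstream assignment unambiguous
    multi_transcript_fraction: float = 0.10
    archetype_fractions: tuple = (0.20, 0.18, 0.18, 0.18, 0.14, 0.12)
    mark_concordance: float = 0.80  # P(mark-2 archetype equals mark-1 archetype)
    stable_fraction: float = 0.85  # archetype-1 genes keeping their profile in B
    depth: float = 2e5  # expected fragments per ChIP sample
    background_fraction: float = 0.35  # share of depth from uniform background
    # expected fragments per anchor at a reference depth of 1e5, by archetype
    amplitudes: dict = field(
        default_factory=lambda: {1: 240.0, 2: 200.0, 3: 160.0, 4: 200.0, 5: 130.0, 6: 55.0}
    )
    bound_prob_core: tuple = (0.30, 0.85)  # P(bound) in (undiff, diff) for core genes
    bound_prob_other: tuple = (0.13, 0.35)
    peak_len: int = 200
    preferred_motif_fraction: float = 0.60  # of condition-B-only summits
    plain_ebox_fraction: float = 0.15  # further fraction given a non-CAGCTG E-box
    n_repressed_targets: int = 12
    repressed_factor_range: tuple = (0.10, 0.25)  # >= 4-fold down
    de_fraction: float = 0.10
    de_factor_range: tuple = (2.5, 6.0)
    flat_jitter: float = 0.15  # flat genes move at most this fraction
    analysis_min_len: int = 4000  # stable core / targets live on filter-eligible genes
    fpkm_meanlog: tuple = tuple(math.log(v) for v in (50.0, 20.0, 15.0, 10.0, 5.0, 1.0))
    fpkm_sdlog: float = 0.8

    def __post_init__(self) -> None:
        if self.n_genes < 60:
            raise ValidationError("need at least 60 genes (10 per archetype)")
        if abs(sum(self.archetype_fractions) - 1.0) > 1e-9:
            raise ValidationError("archetype fractions must sum to 1")
        if self.depth < 1e4:
            raise ValidationError("depth must be >= 1e4 fragments")


@dataclass
class SyntheticDataset:
    """Paths of one generated dataset plus its in-memory ground truth."""

    outdir: Path
    genome: Path
    annotation: Path
    coverage: dict  # (mark, condition) -> bedGraph path
    inputs: dict  # condition -> bedGraph path
    peaks: dict  # condition -> narrowPeak path
    expression: Path
    truth_path: Path
    truth: dict


def archetype_shapes(window: WindowSpec | None = None) -> dict[int, np.ndarray]:
    """Per-archetype expected-signal shapes over the window bins (sum to 1)."""
    window = window or WindowSpec()
    x = window.bin_edges()[:-1] + window.bin_bp / 2.0  # oriented bin centres

    def gauss(mu: float, sd: float) -> np.ndarray:
        g = np.exp(-0.5 * ((x - mu) / sd) ** 2)
        return g / g.sum()

    plateau = np.where(x > 0, 1.0, 0.15)
    shapes = {
        1: plateau / plateau.sum(),
        2: 0.5 * gauss(-300, 300) + 0.5 * gauss(700, 350),
        3: gauss(300, 200),
        4: gauss(-1000, 500),
        5: gauss(500, 1200),  # low broad dome over the TSS region
        6: np.full(window.n_bins, 1.0 / window.n_bins),  # near-background
    }
    return shapes


def _write_fasta(path: Path, seqs: Mapping[str, np.ndarray]) -> None:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for name, codes in seqs.items():
            fh.write(f">{name}\n")
            seq = bases[codes].tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    Faidx(str(path), rebuild=True)


def generate_genome_and_annotation(
    outdir: str | Path, seed: int, params: SimulationParams | None = None
) -> dict:
    """Write ``genome.fa`` and ``genes.bed`` (BED12); return the partial truth.

    Genes are non-overlapping, on both strands, with ~``short_fraction``
    shorter than 4 kb to exercise the length filter; starts, ends and hence
    TSS fall on the 100-bp coverage grid.  Archetypes per mark x condition
    and the per-gene stability flag are drawn here.
    """
    params = params or SimulationParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chroms = {f"chr{i + 1}": rng.integers(0, 4, size=params.chrom_length, dtype=np.int8)
              for i in range(params.n_chroms)}

    genes: dict[str, dict] = {}
    chrom_names = list(chroms)
    chrom_i = 0
    cursor = 20_000
    for gi in range(params.n_genes):
        short = rng.random() < params.short_fraction
        if short:
            length = int(rng.integers(20, 40)) * 100  # 2.0-3.9 kb
        else:
            length = int(rng.integers(42, 121)) * 100  # 4.2-12.0 kb
        gap = params.intergenic_gap + int(rng.integers(0, 21)) * 100
        start = cursor + gap
        while start + length > params.chrom_length - 15_000:
            chrom_i += 1
            if chrom_i >= len(chrom_names):
                raise GenerationError(
                    "genes cannot be placed without overlap; "
                    "increase chrom_length or n_chroms"
                )
            cursor = 20_000
            start = cursor + gap
        chrom = chrom_names[chrom_i]
        cursor = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"g{gi + 1:04d}"

        arch = {}
        base = int(rng.choice(np.arange(1, 7), p=params.archetype_fractions))
        for mi, mark in enumerate(MARKS):
            if mi == 0 or rng.random() < params.mark_concordance:
                a = base
            else:
                a = int(rng.choice(np.arange(1, 7), p=params.archetype_fractions))
            arch[mark] = {"undiff": a}
        in_cluster1 = any(arch[m]["undiff"] == 1 for m in MARKS)
        stable = (not in_cluster1) or (rng.random() < params.stable_fraction)
        for mark in MARKS:
            a = arch[mark]["undiff"]
            if stable or a != 1:
                arch[mark]["diff"] = a
            else:
                arch[mark]["diff"] = int(rng.integers(2, 7))

        genes[gene_id] = {
            "chrom": chrom,
            "strand": strand,
            "start": start,
            "end": start + length,
            "tss": start if strand == "+" else start + length - 1,
            "length": length,
            "archetype": arch,
            "stable": bool(stable),
            "n_transcripts": 2 if (not short and rng.random() < params.multi_transcript_fraction) else 1,
        }

    _write_fasta(outdir / "genome.fa", chroms)

    with open(outdir / "genes.bed", "w") as fh:
        for gene_id, g in genes.items():
            records = [(g["start"], g["end"], f"{gene_id}|{gene_id}.t1")]
            if g["n_transcripts"] == 2:
                # second isoform shares the TSS but ends 300 bp earlier
                if g["strand"] == "+":
                    records.append((g["start"], g["end"] - 300, f"{gene_id}|{gene_id}.t2"))
                else:
                    records.append((g["start"] + 300, g["end"], f"{gene_id}|{gene_id}.t2"))
            for s, e, name in records:
                size = e - s
                fh.write(
                    f"{g['chrom']}\t{s}\t{e}\t{name}\t0\t{g['strand']}"
                    f"\t{s}\t{e}\t0\t1\t{size},\t0,\n"
                )

    core = sorted(
        gid for gid, g in genes.items()
        if g["length"] >= params.analysis_min_len
        and all(g["archetype"][m][c] == 1 for m in MARKS for c in CONDITIONS)
    )
    return {
        "seed": seed,
        "genes": genes,
        "stable_core": core,
        "chromosomes": {name: params.chrom_length for name in chroms},
    }


def simulate_coverage(
    truth: dict,
    outdir: str | Path,
    seed: int,
    params: SimulationParams | None = None,
    window: WindowSpec | None = None,
) -> dict:
    """Write per-(mark, condition) bedGraph tracks plus matched input tracks.

    Expected counts per 100-bp bin are amplitude x archetype shape plus a
    uniform background; realised counts are Poisson.  The input track is
    background-only at matched library depth (same expected total as a ChIP
    sample), so per-million normalisation leaves a small uniform
    subtraction bias equal to the sample's signal share — the weakest
    archetype sits close to that bias, which is what makes the row-sum
    filter bite.  Library sizes are embedded as ``# total_mapped_reads=N``
    headers and recorded in the truth.
    """
    params = params or SimulationParams()
    window = window or WindowSpec()
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    shapes = archetype_shapes(window)
    bin_bp = window.bin_bp
    n_bins = {c: length // bin_bp for c, length in truth["chromosomes"].items()}
    total_bins = sum(n_bins.values())
    bg_per_bin = params.depth * params.background_fraction / total_bins
    depth_scale = params.depth / 1e5
    mean_amp = sum(
        f * params.amplitudes[c + 1] for c, f in enumerate(params.archetype_fractions)
    )
    expected_signal = params.n_genes * mean_amp * depth_scale
    input_per_bin = (expected_signal + params.depth * params.background_fraction) / total_bins

    def write_track(path: Path, counts: Mapping[str, np.ndarray]) -> int:
        total = int(sum(int(v.sum()) for v in counts.values()))
        with open(path, "w") as fh:
            fh.write(f"# total_mapped_reads={total}\n")
            for chrom in sorted(counts):
                v = counts[chrom]
                change = np.flatnonzero(np.diff(v) != 0) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(v)]])
                for s, e in zip(starts, ends):
                    if v[s] > 0:
                        fh.write(f"{chrom}\t{s * bin_bp}\t{e * bin_bp}\t{int(v[s])}\n")
        return total

    files: dict = {"coverage": {}, "inputs": {}}
    library_sizes: dict[str, int] = {}
    up_bins = window.upstream_bp // bin_bp
    down_bins = window.downstream_bp // bin_bp

    for mark in MARKS:
        for cond in CONDITIONS:
            counts = {c: rng.poisson(bg_per_bin, size=n).astype(np.int64)
                      for c, n in n_bins.items()}
            for g in truth["genes"].values():
                arch = g["archetype"][mark][cond]
                amp = params.amplitudes[arch] * depth_scale
                if amp <= 0:
                    continue
                expected = amp * shapes[arch]
                signal = rng.poisson(expected)
                if g["strand"] == "+":
                    b0 = (g["tss"] - window.upstream_bp) // bin_bp
                    counts[g["chrom"]][b0 : b0 + window.n_bins] += signal
                else:
                    b0 = (g["tss"] + 1 - window.downstream_bp) // bin_bp
                    counts[g["chrom"]][b0 : b0 + window.n_bins] += signal[::-1]
            path = outdir / f"{mark}_{cond}.bedGraph"
            library_sizes[f"{mark}_{cond}"] = write_track(path, counts)
            files["coverage"][(mark, cond)] = path
    for cond in CONDITIONS:
        counts = {c: rng.poisson(input_per_bin, size=n).astype(np.int64)
                  for c, n in n_bins.items()}
        path = outdir / f"input_{cond}.bedGraph"
        library_sizes[f"input_{cond}"] = write_track(path, counts)
        files["inputs"][cond] = path

    truth["library_sizes"] = library_sizes
    return files


def simulate_peaks_motifs(
    truth: dict,
    genome_path: str | Path,
    outdir: str | Path,
    seed: int,
    params: SimulationParams | None = None,
) -> dict:
    """Write per-condition narrowPeak files and plant E-boxes under summits.

    Bound-gene sets are nested (condition B is a superset), with higher
    binding probabilities for the truth stable core.  One 200-bp peak per
    bound gene sits within the gene's own assignment region.  CAGCTG is
    written into the genome at a fraction of condition-B-only summits, a
    further fraction gets a non-preferred CANNTG, and the planted
    "repressed target" subset is drawn from stable-core genes carrying the
    preferred motif.  Every edit is recorded in the truth.
    """
    params = params or SimulationParams()
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    core = set(truth["stable_core"])

    planted_windows: list[tuple[str, int]] = []
    bound = {c: [] for c in CONDITIONS}
    fasta = Fasta(str(genome_path), mutable=True)
    try:
        for gene_id, g in truth["genes"].items():
            p_a, p_b = (params.bound_prob_core if gene_id in core
                        else params.bound_prob_other)
            u = rng.random()
            bound_a, bound_b = u < p_a, u < p_b  # nested: B is a superset of A
            d = int(rng.integers(3, 26)) * 100  # summit-side offset from the TSS
            if g["strand"] == "+":
                start = g["tss"] - d - params.peak_len
            else:
                start = g["tss"] + d
            end = start + params.peak_len
            summit = start + params.peak_len // 2
            # defensive: keep planted summit windows disjoint (re-placement logged)
            while any(g["chrom"] == c and abs(summit - s) < 40 for c, s in planted_windows):
                logger.info("%s: summit window collision; re-placing peak", gene_id)
                d += 100
                start = (g["tss"] - d - params.peak_len if g["strand"] == "+"
                         else g["tss"] + d)
                end = start + params.peak_len
                summit = start + params.peak_len // 2
            g["bound"] = {"undiff": bool(bound_a), "diff": bool(bound_b)}
            g["peak"] = {"start": start, "end": end, "summit": summit} if bound_b else None
            g["motif"] = None
            if bound_a:
                bound["undiff"].append(gene_id)
            if bound_b:
                bound["diff"].append(gene_id)
            if bound_b and not bound_a:
                r = rng.random()
                motif = None
                if r < params.preferred_motif_fraction:
                    motif = "CAGCTG"
                elif r < params.preferred_motif_fraction + params.plain_ebox_fraction:
                    nn = ["AA", "AT", "TA", "TT", "CA", "AC", "GT", "TG"][int(rng.integers(0, 8))]
                    motif = f"CA{nn}TG"
                if motif is not None:
                    fasta[g["chrom"]][summit - 3 : summit + 3] = motif
                    planted_windows.append((g["chrom"], summit))
                    g["motif"] = {"pattern": motif, "position": summit - 3,
                                  "preferred": motif == "CAGCTG"}
    finally:
        fasta.close()

    files = {}
    for cond in CONDITIONS:
        path = outdir / f"myod_{cond}.narrowPeak"
        with open(path, "w") as fh:
            for gene_id in bound[cond]:
                g = truth["genes"][gene_id]
                pk = g["peak"]
                fh.write(
                    f"{g['chrom']}\t{pk['start']}\t{pk['end']}\t{cond}_pk_{gene_id}\t0\t."
                    f"\t5.0\t-1\t-1\t{pk['summit'] - pk['start']}\n"
                )
        files[cond] = path

    candidates = sorted(
        gid for gid in core
        if truth["genes"][gid]["bound"]["diff"]
        and not truth["genes"][gid]["bound"]["undiff"]
        and truth["genes"][gid]["motif"]
        and truth["genes"][gid]["motif"]["preferred"]
    )
    n_targets = min(params.n_repressed_targets, len(candidates))
    if n_targets < params.n_repressed_targets:
        logger.warning(
            "only %d candidate repressed targets available (requested %d)",
            n_targets, params.n_repressed_targets,
        )
    targets = sorted(rng.choice(candidates, size=n_targets, replace=False).tolist())
    truth["bound_genes"] = {c: sorted(bound[c]) for c in CONDITIONS}
    truth["repressed_targets"] = targets
    return files


def simulate_expression(
    truth: dict, outdir: str | Path, seed: int, params: SimulationParams | None = None
) -> Path:
    """Write the FPKM table; fold changes are anti-correlated with TF gain.

    Baseline FPKM is log-normal with archetype-dependent location (archetype
    1 highest, 6 lowest).  Repressed targets drop >= 4-fold in condition B;
    a fraction of other genes moves >= 2.5-fold in either direction, except
    that non-target stable-core TF gainers never go down (they are the
    negative controls of the funnel); everything else stays flat.
    """
    params = params or SimulationParams()
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    targets = set(truth["repressed_targets"])
    core = set(truth["stable_core"])

    lines = ["gene_id\tfpkm_undiff\tfpkm_diff"]
    for gene_id, g in truth["genes"].items():
        arch = g["archetype"]["H3K4me2"]["undiff"]
        base = float(rng.lognormal(params.fpkm_meanlog[arch - 1], params.fpkm_sdlog))
        gainer = g["bound"]["diff"] and not g["bound"]["undiff"]
        if gene_id in targets:
            factor = float(rng.uniform(*params.repressed_factor_range))
            cls = "repressed"
        elif rng.random() < params.de_fraction:
            f = float(rng.uniform(*params.de_factor_range))
            up = rng.random() < 0.5
            if gene_id in core and gainer:
                up = True  # keep the funnel's negative controls out of "down"
            factor = f if up else 1.0 / f
            cls = "de_up" if up else "de_down"
        else:
            factor = float(rng.uniform(1 - params.flat_jitter, 1 + params.flat_jitter))
            cls = "flat"
        fpkm_a = max(round(base, 4), 1e-4)
        fpkm_b = max(round(base * factor, 4), 1e-4)
        g["fpkm"] = [fpkm_a, fpkm_b]
        g["expression_class"] = cls
        lines.append(f"{gene_id}\t{fpkm_a}\t{fpkm_b}")
    path = outdir / "expression.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def simulate_dataset(
    outdir: str | Path, seed: int, params: SimulationParams | None = None
) -> SyntheticDataset:
    """Generate the full dataset under ``outdir`` and serialise the truth.

    All randomness derives from ``seed`` (stage streams are spawned from
    it), so repeated calls are byte-identical.
    """
    params = params or SimulationParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_genome, s_cov, s_peaks, s_expr = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(4)
    ]
    truth = generate_genome_and_annotation(outdir, s_genome, params)
    truth["seed"] = seed
    genome = outdir / "genome.fa"
    peak_files = simulate_peaks_motifs(truth, genome, outdir, s_peaks, params)
    expression = simulate_expression(truth, outdir, s_expr, params)
    cov_files = simulate_coverage(truth, outdir, s_cov, params)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return SyntheticDataset(
        outdir=outdir,
        genome=genome,
        annotation=outdir / "genes.bed",
        coverage=cov_files["coverage"],
        inputs=cov_files["inputs"],
        peaks=peak_files,
        expression=expression,
        truth_path=truth_path,
        truth=truth,
    )


def load_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
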