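# profileclust

Clustering of histone-modification profile *shapes* around transcription
start sites, with integration of transcription-factor binding, binding-site
motifs and gene expression across two cellular conditions.

The package is written for regulatory genomicists who have, for two
conditions (for example undifferentiated myoblasts and differentiated
myotubes), ChIP coverage for one or more histone marks (such as H3K4me2 and
H3K4me3) with matched input, a transcription-factor peak set with summits
(such as MyoD), a genome, gene models and an FPKM expression table — and who
want to know which genes keep a distinctive chromatin profile across the
transition and how TF binding at those genes relates to expression change.

## The method

For every unique TSS of transcripts ≥ 4 kb, ChIP signal is summed in 100-bp
bins over the oriented window [−2 kb, +4 kb), normalised per million mapped
reads. The matched input is subtracted bin-wise and anchors whose 6-kb total
is ≤ 0 are discarded. The retained *n* × 60 matrix is clustered with seeded
k-means (k = 6, best of 10 restarts by within-cluster sum of squares):

&nbsp;&nbsp;&nbsp;&nbsp; argmin<sub>C</sub> Σ<sub>c</sub> Σ<sub>i∈c</sub> ‖x<sub>i</sub> − μ<sub>c</sub>‖²

Clusters are renumbered canonically (cluster 1 = gene-body-enriched, last =
lowest signal) and verified by Fisher linear discriminant analysis with
stratified cross-validated nearest-centroid accuracy. Clusters from the two
conditions are paired by the overlap-maximising bipartite assignment; the
*stability* of a cluster is the fraction of its genes recovered in the
matched cluster. TF peaks are assigned to a gene when they overlap the
transcribed region or 10 kb upstream of the TSS (strand-aware); genes are
classified as gaining, losing or constitutively carrying a peak. A 30-bp
window centred on each peak summit is scanned for the E-box class CANNTG
(reverse-complement closed, so a forward scan is strand-complete) and the
preferred variant CAGCTG. Expression change is a single-replicate max/min
fold change with pseudocount 1, called differential at FC ≥ 2. All layers
join into the nested funnel

&nbsp;&nbsp;&nbsp;&nbsp; stable cluster-1 core ⊇ TF gain ⊇ differential ⊇ down-regulated ⊇ preferred E-box,

whose final members are candidate directly repressed TF targets. Exact
statistics (upper-tail hypergeometric overlap, two-sided Fisher with the
point-probability criterion, exact/asymptotic Mann-Whitney, Benjamini-
Hochberg control) back every reported comparison.

A synthetic-data generator emulates the full study design — six planted
profile archetypes per mark and condition, a configurable stable fraction,
nested bound-gene sets, E-boxes written into the genome under gained
summits, and a planted repressed-target subset — and serialises the ground
truth, so every stage can be validated end to end.

## A worked example

```bash
python examples/03_binding_motifs_funnel.py
```

prints, for the seed-17 reference simulation:

```
genes with stable cluster-1 profiles in both marks and conditions: 73
  of these, gaining a TF peak upon differentiation: 37
    of these, differentially expressed (FC >= 2):   14
      of these, down-regulated:                     12
        of these, preferred E-box (CAGCTG) at the summit: 12
final candidate repressed targets: g0003, g0054, g0174, ...
planted truth recovered: True (12/12 targets)
undiff: 27% of common cluster-1 genes TF-bound (two-sided Fisher p = 0.0026 vs all other clusters)
diff: 82% of common cluster-1 genes TF-bound (two-sided Fisher p = 1.1e-15 vs all other clusters)
```

Reading: 73 genes keep a cluster-1 (gene-body-enriched) profile for both
marks in both conditions; 37 of them acquire a TF peak upon differentiation;
12 of those are ≥ 2-fold down-regulated and carry the preferred E-box under
the gained summit — and they are exactly the 12 genes the simulation planted
as directly repressed targets. Cluster-1 genes are far more often TF-bound
than the rest of the genome, especially after differentiation.

The other examples cover profile clustering against planted archetypes
(`01`), cross-condition stability (`02`) and the exact statistics on
hand-checkable inputs (`04`). The same pipeline runs from the shell:

```bash
profileclust simulate --seed 17 --out dataset/
profileclust run --dataset dataset/ --seed 17 --out results/
```

Per-stage subcommands (`anchors`, `matrix`, `cluster`, `compare`, `assign`,
`scan`, `integrate`, `enrich`) expose each step on TSV/BED/narrowPeak/FASTA
inputs; `docs/methods.md` documents the model, parameters and their
defaults.

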