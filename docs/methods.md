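# Methods

## Signal model and window geometry

All coordinates are 0-based half-open (BED convention). The TSS of a
transcript is its first transcribed base: `start` on the plus strand,
`end − 1` on the minus strand. Transcripts are deduplicated on
(chrom, strand, start, end), filtered to ≥ 4 kb (inclusive; shorter genes
cannot carry a −2 kb/+4 kb profile without bleeding into neighbours), and
collapsed to unique (chrom, strand, TSS) anchors that union their transcript
and gene identifiers. A gene with several distinct TSS contributes several
anchors and may therefore belong to several clusters.

The window covers oriented offsets [−2000, +4000) in 100-bp bins (60 bins).
Oriented offset *o* maps to genomic position `tss + o` on the plus strand and
`tss − o` on the minus strand, so offset 0 is the TSS base itself on both
strands; bins beyond chromosome ends contribute zeros (windows are
zero-padded, not dropped, keeping the row count deterministic). Bin values
are total coverage mass over the bin scaled by 10⁶ / library size. Coverage
comes from 4-column bedGraph (library size passed explicitly or as a
`# total_mapped_reads=N` header) or from single-end alignments extended
3′-ward to the fragment size and piled up; alignments are streamed
sequentially, so no index is needed and plain-text SAM works.

Input subtraction is bin-wise on the per-million scale; rows whose 6-kb
total after subtraction is ≤ 0 are discarded. This single row-level rule is
the package's only input filter. Bin-level negatives are kept by default
(`clamp_negative` floors them at zero): the filter is defined on totals and
clamping would bias low-signal profiles upward.

## Clustering and verification

k-means uses Lloyd iterations on the raw subtracted rows — no per-row
scaling, because absolute signal level is informative (it couples with
expression) — with k = 6, an iteration cap of 10⁶, and 10 restarts, each
initialised from k distinct rows drawn from a generator seeded by the
user's seed; the restart with the lowest within-cluster sum of squares
wins, making the partition a deterministic function of (seed, row order).
A `row_normalize` option exists but is off by default. k is a configuration
value; no automatic selection is attempted.

Cluster numbers from k-means are arbitrary run artifacts, so results are
canonically renumbered: label 1 goes to the cluster with the highest mean
centroid signal over gene-body bins (oriented offsets ≥ +1 kb), the rest
follow by descending total centroid signal, ties break to the lower
original label. The renumbering is idempotent and stable under row
permutation.

The partition is verified with Fisher linear discriminant analysis: pooled
within-class scatter regularised by `ridge × trace/dim` on the diagonal
(default ridge 10⁻⁶), generalised eigenvectors of the between/within
problem, projection onto the first two axes for display, and stratified
5-fold cross-validated nearest-class-centroid accuracy in the full (k−1)-
dimensional discriminant space. On label-shuffled data this accuracy falls
to chance (1/k), which is the negative control.

## Cross-condition comparison

Gene-level membership is the union over a gene's retained anchors.
Clusters from two conditions are paired by the assignment that maximises
total gene overlap (Hungarian algorithm); with canonical renumbering the
expected pairing is the identity and deviations are logged. Stability of
cluster *c* is |genes in c(A) ∩ genes in match(c)(B)| / |genes in c(A)|.
Stability is reported at gene level, matching how such fractions are
usually quoted. Cluster-1 gene sets from the two marks are intersected per
condition (overlap significance by upper-tail hypergeometric test), and the
intersection of those common sets across conditions is the *stable core*.

## Peaks, motifs, expression

A peak (ENCODE narrowPeak; column 10 is the summit offset, −1 falls back to
the midpoint, logged) is assigned to a gene when its interval overlaps the
gene's eligible region — transcribed region plus 10 kb upstream of the TSS,
strand-aware. Overlap of the whole peak interval is the default reading of
"located within"; a summit-containment mode is available. Assignment runs
on the full (unfiltered) transcript set; reporting is then restricted to
the analysis universe, separating geometry from bookkeeping. Genes are
classified gain / loss / constitutive / none between conditions, and
per-cluster bound percentages are tested with the two-sided Fisher exact
test against all other clusters.

Summit windows are [summit − 15, summit + 15) (half-open symmetry for the
even window length), truncated at chromosome ends, uppercased. The E-box
class CANNTG and the MyoD-preferred variant CAGCTG are both closed under
reverse complement, so a forward-strand scan is strand-complete; `N` in a
pattern matches any base, `N` in the sequence matches nothing (unknown
bases must not create motifs); a full 6-mer must fit inside the window.

Expression uses a single-replicate fold change FC = max(a+ε, b+ε) /
min(a+ε, b+ε) with pseudocount ε = 1 FPKM and the inclusive threshold
FC ≥ 2; direction is the sign of b − a for differential genes, and a signed
log2 FC column is also emitted. This matches a single-library design; no
dispersion model is fitted. The integration step performs a full outer
join of all evidence layers per gene (missing expression is marked and
excluded from differential counts) and reports the funnel
core ⊇ gain ⊇ differential ⊇ down ⊇ preferred-motif, which is monotone by
construction.

## Exact statistics

* Hypergeometric overlap: upper tail P(X ≥ k) via the survival function.
* Two-sided Fisher: sum of probabilities of all same-margin tables whose
  point probability is ≤ that of the observed table, with relative
  tolerance 10⁻⁷ guarding floating-point ties.
* Mann-Whitney: exact permutation distribution when the combined sample is
  ≤ 20 without ties (enumeration is cheap there), otherwise the normal
  approximation with tie and continuity corrections. The approximation is
  accurate in the distribution body but can deviate tens of percent in the
  far tail (p < 0.05) at such sizes — the exact route covers that regime.
* Benjamini-Hochberg step-up adjustment with cumulative-minimum
  enforcement, capped at 1, input order preserved.
* Gene-set enrichment: one 2×2 Fisher test per reference set against the
  universe, BH across sets, significant at adjusted p ≤ α (default 0.01).
  Reference sets are read from GMT files.

These are validated in the test suite against rational-arithmetic
enumeration oracles (exact fractions) on all small problems, and the
scanner and peak assignment against brute-force references.

## The synthetic-data generator

The generator emulates the statistical structure of a two-condition
differentiation study: 600 genes on two 7-Mb chromosomes, both strands,
~10% shorter than the 4-kb filter; gene starts and ends on the 100-bp
coverage grid so planted windows align with bins; intergenic gaps ≥ 13 kb
so that 10-kb-upstream peak assignment is unambiguous by construction
(the default chromosome budget follows from these spacing requirements).
About 10% of eligible genes carry a second isoform sharing the TSS.

Six profile archetypes drive coverage (fractions 0.20/0.18/0.18/0.18/
0.14/0.12): gene-body plateau, bimodal TSS, narrow TSS, upstream peak, a
low broad dome, and a very-low uniform class. Expected fragments per
anchor at a 10⁵-fragment reference depth are 240/200/160/200/130/55,
scaled linearly by the configured depth (default 2×10⁵ fragments per
sample, roughly 1000× below a real library so that generation takes
seconds); per-bin counts are Poisson (an over-dispersion knob is out of
scope; Poisson is the simplest model that exercises the pipeline).
Background is uniform at 35% of depth; the matched input is background-only
at the same expected total as a ChIP sample. Per-million input subtraction
therefore leaves a small uniform negative bias equal to the sample's signal
share — exactly the regime in which the row-sum filter operates: the
very-low class sits just above that bias and loses roughly a tenth of its
rows, while all six classes remain recoverable. Amplitudes and shapes were
chosen so that archetype mean-profile separations exceed about five times
the projected noise SD, the regime in which k-means recovery is reliable;
below that, classes merge and the spare centroid splits a strong class.

The second mark shares a gene's archetype with probability 0.8. A stable
flag per gene (0.85 for cluster-1 genes, the planted stability) keeps
archetypes identical in the second condition; unstable cluster-1 genes are
reassigned. Bound-gene sets are nested (condition B ⊇ A) with binding
probabilities (0.30, 0.85) for truth-core genes and (0.13, 0.35) otherwise;
each bound gene gets one 200-bp peak inside its own assignment region.
CAGCTG is written into the genome under 60% of condition-B-only summits
(a further 15% get a non-preferred CANNTG); 12 repressed targets are drawn
from filter-eligible stable-core genes with a planted preferred motif and
down-regulated 4–10-fold. Baseline FPKM is log-normal with archetype-
dependent location (archetype 1 highest); 10% of other genes move
≥ 2.5-fold (never down for non-target stable-core TF gainers, which serve
as the funnel's negative controls), the rest stay within ±15%. All planted
facts go to `truth.json`; recovery tests read only that file.

What the generator does **not** emulate: mappability and GC artifacts,
fragment-length distributions, read-level noise (coverage is rendered at
bin resolution), overdispersion, replicate structure, enhancer-range
(> 10 kb) regulation, and genes whose isoforms start at different TSS.
Passing tests therefore demonstrate correctness of the pipeline's
computations and calibration of its statistics under the planted model —
not robustness to artifacts of real libraries.

## Numerical and design choices

* Per-million normalisation happens before subtraction in both matrices.
* Chromosome-edge windows are zero-padded; absent chromosomes give zero
  rows plus a warning rather than errors.
* Empty clusters during Lloyd iterations are re-seeded from the farthest
  points (scikit-learn's relocation rule).
* k-means ties and restart selection are resolved by inertia; canonical
  relabel ties break to the lower original label.
* The discriminant variant (Fisher LDA) and the cluster-matching rule
  (optimal assignment rather than greedy or visual pairing) are this
  package's choices where the underlying procedure is usually left
  unspecified; both are flagged in the API documentation.
* Fold change is max/min (unsigned) with a signed log2 column alongside,
  covering both conventions.
* The reference null calibration uses a 1200-gene universe with ~30%
  binding so that two-sided Fisher p-values are nearly continuous; with
  discrete support the exact test is conservative and a plain
  uniformity check would reject on granularity alone.

## Problem sizes

The test suite and the acceptance script run the reference design (600
genes, two 7-Mb chromosomes, 2×10⁵ fragments per sample, seed 17; five
seeds for the stability aggregate; 200 null simulations for calibration and
500 for the BH rate; exhaustive oracle enumeration up to population 30).
One full dataset generates in a few seconds and occupies ~30 MB on disk;
the complete suite finishes in well under a minute of compute after
package import.

## Known limitations

Stability estimates conflate planted profile switching with residual
clustering error (the two are unidentifiable at gene level); with the
default separations the error term is ≪ 1%. The funnel's exactness on
synthetic data relies on unambiguous peak assignment guaranteed by the
generator's spacing; on real data one peak can serve several genes and the
funnel becomes a candidate list, not a proof of direct regulation. The
Mann-Whitney asymptotic tail and the discreteness of exact tests are
documented above. GO-style annotation retrieval is out of scope: enrichment
runs against user-supplied gene sets only.
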