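# Methods

`clonemem` reimplements, as a tested library, the computational core of a
single-cell study of clonally heritable epigenetic memory: cells carry
expressed lineage barcodes read out alongside chromatin accessibility and
transcription, so clone identity, motif-level chromatin state and gene
expression are all measured in the same cell.  This note records the models,
the defaults and the places where the design was genuinely open.

## Clone calling from expressed barcodes

The barcode vector embeds a 48-bp random barcode behind a constant anchor
7-mer (`TAGACAT`).  The 48-mer is structured: eight blocks of four random
bases, each followed by a fixed 2-mer (`CT, AC, TC, GT, TG, CA, AT, GC`),
i.e. the oligo `NNNNCT…NNNNGC`.  The parser finds the first read window
within Hamming distance 1 of the anchor, trims it and everything before it,
and validates the stagger 2-mers at offsets 4, 10, …, 46; reads with all-G
UMIs are rejected (a poly-G run is the signature of a failed Illumina
cycle, not a molecule).  Every read falls in exactly one category:
accepted, `NO_ANCHOR`, `SHORT`, `POLYG_UMI`, `INVARIANT_FAIL`.  The
invariant offsets live on the template type as data, not as magic numbers —
an off-by-one there is the most dangerous bug in the module, so the
template is tested against the published oligo layout directly.

Sequencing errors are collapsed in two stages on Levenshtein (full edit)
distance, computed with `edlib`: each observed barcode maps to the most
abundant barcode within distance 4 of it; among the resulting
representatives, anything within distance 2 of a more abundant
representative collapses to it (one pass).  Ties in abundance break
lexicographically, which also rules out collapse cycles.  The final
consensus set is asserted to be pairwise separated by more than 2 edits;
violation is an error, not a silent merge.  Cells join the clone supported
by the plurality of their UMIs (ties → excluded as ambiguous, to avoid
nondeterminism); clones need at least 5 cells; each clone is assigned to
the sample contributing most of its member cells, with that majority
fraction reported as purity.  Cell-count majority (not read-count) is the
assignment criterion; read-level support is visible in the QC output.

## Deviation scoring

For an annotation set m (peaks carrying a motif, or a weighted gene
program) and cell i, the expected signal is `E[i,m] = depth_i · Σ_{j∈m} w_j
f_j`, with `f_j` feature j's fraction of all counts.  The raw deviation
`(obs − E)/E` is z-scored against 250 background sets, each built by
resampling every member feature from its mean-abundance bin (20 equal-size
bins for genes, deciles for peaks), keeping the member's weight.  This is
the standard background-corrected deviation construction; one deliberate
simplification is that background peaks are matched on mean accessibility
only — synthetic peaks have no sequence, so GC matching is meaningless
here, and the bin count is a parameter should composition matching ever be
added.  Cells with E = 0 get NaN and drop out of summaries.

Gene programs come from latent Dirichlet allocation on raw (unnormalised,
unbinarised) counts; one model per topic number in the requested range, the
model with the highest log-likelihood wins.  Programs are scored with the
same deviation code path, substituting the topic-by-gene probability rows
for the motif-by-peak membership matrix.  At desk scale the tests fit topic
ranges like {3, 5, 8} on a few hundred cells; the 30–90 range typical of
full-size experiments is a configuration choice, not a code path
difference.  A program's reportable gene list is its top 150 genes by
weight.

Motifs are bagged into families greedily: sort by cross-cell score SD, walk
down the list, join the first existing leader with similarity q ≤ 0.05,
otherwise become a leader.  The similarity/q matrix is an input (it comes
from sequence comparison tooling upstream); missing entries count as
dissimilar, asymmetric entries as the minimum of the two directions.
"Most variable" for the per-sample tests means SD of per-sample mean
scores; the t-test is Welch's (robust default at sample-level n of ~5),
BH-adjusted across the 50 most variable families.

Fixed thresholds, with their exact boundary semantics:
activated cells are *strictly above* 1.5; high-memory clones have median
score *strictly above* 1.25; memory footprints gain *at least* 0.2; adenoma
bins have smoothed z of *at least* 1; high-program tumors score *strictly
above* 1.5.

## The clonal-heritability permutation test

For one feature: within-clone SDs (n−1 denominator; clones under 2 cells
excluded), the median across clones, squared.  That statistic literally
squares the median SD — an unusual but deliberate construction (the median
is robust to a few noisy clones; squaring puts it on a variance scale).
Heritability shows up as the observed statistic falling *below*
its permutation null (clone members resemble each other, so within-clone
spread shrinks).  The null: 1000 random permutations of the cell→clone
assignment (sizes preserved), shared across features so cross-feature
comparisons ride on the same permutations; then `Z = (obs − mean)/sd` over
the null draws and `p = 2Φ(−|Z|)`, BH across features.  The normal
approximation is the primary reported test; because the null of a squared median
can be skewed, an exact rank-based permutation p-value is reported
alongside as a diagnostic.  A zero-SD null (e.g. a single clone) is flagged
degenerate with p = 1.  The permutation loop is vectorised with
`np.add.reduceat` over clone-sorted rows: 1000 permutations × 500 features
× 1000 cells runs in a few seconds.

Clone-level comparisons: per-clone median/SD summaries, a two-sample KS
test on the SDs between conditions, median shifts, and the fraction of
clones above the high threshold per condition.  Motif–program coupling is
the Pearson correlation of clone-mean score vectors (Spearman would be a
one-line change; Pearson matches how the coupling is defined).

## k-NN enrichment and smoothing

Enrichment: per cell, the observed fraction of each condition among its
k = 100 Euclidean nearest neighbors (self excluded — including self biases
toward the own condition by 1/k) minus the global condition fraction among
the analysed cells.  Rows sum to zero by construction.  Smoothing replaces
each value with the mean over self plus k = 20 neighbors; including self is
the common convention and is configurable.  Search is exact; ties at equal
distance break by cell index so results are reproducible.

## Footprint co-binding

Footprint scores arrive binned at 10 bp.  Bins whose maximum score across
conditions is below 0.2 are excluded; surviving scores are mapped to their
empirical uniform quantiles within each condition (scikit-learn's quantile
transform), making conditions comparable.  Memory sites are bins gaining at
least 0.2 over the batch-matched control (the pairing is explicit
configuration, never inferred); the same machinery calls losses with
`sign=-1`.  The 0.2 delta is applied to transformed scores by default, with
the raw-score alternative one flag away.

Co-binding between two TF families: classify every peak in the filtered
universe as containing memory sites of both, the first only, the second
only, or neither; take the 2×2 odds ratio (Haldane–Anscombe +0.5 on all
cells when any cell is zero, keeping the OR finite), log2 it, then across
all pairs clip positive values to their 10th–90th percentile range and
rescale to [0, 1] (negatives to [−1, 0]; a degenerate range maps its class
to ±1).  Values below the 10th percentile clip to 0, so the score's sign
matches the log2 OR except at that floor.  Distances between families are
all |midpoint − midpoint| pairs of their memory sites within a shared peak.
The footprint-vs-binding sweep reports sensitivity and specificity of
predicting differential peaks at every threshold over the per-peak deltas
(peak delta = largest-magnitude site delta after merging overlapping
sites).

## Genomic bookkeeping

Coordinates are 0-based half-open throughout.  Summit filtering pads each
summit by 400 bp to an 801-bp window, walks summits in decreasing
significance (ties by chrom, position), keeps a summit iff its padded
window is clear of all previously kept windows, and resizes kept summits to
summit ± 150 (301 bp).  Overlap is judged on the padded windows, matching
the stated order of operations; starts clamp at 0 for summits within 400 bp
of a chromosome start (peaks within 150 bp of the start will be shorter
than 301 bp — such summits do not occur in practice).  Pseudobulks are
integer column sums (conservation is exact), RPM is per-million of the
group total, and the expression filter keeps features reaching RPM ≥ 10 in
at least one group.  Variable-peak selection requires ≥ 20 raw reads in
some sample, then ranks by RPM SD and keeps the top 10,000.  Per-feature
z-scores use the n−1 SD across samples; "change" subtracts the control-mean
z.

## Spatial tumors

Bins under 300 reads are dropped; survivors are rescaled to the mean
retained depth.  Adenoma bins: PCA (20 components) of log2(x+1) normalised
counts, marker expression mean-smoothed over k = 20 neighbors in PC space,
z-scored, called at z ≥ 1.  Tumors: Louvain communities on the k = 5
spatial nearest-neighbor graph of adenoma bins only (seeded, hence
deterministic).  The resolution parameter defaults to 0.1: on graphs of a
few hundred bins, resolution 1 reliably splits one contiguous blob into
several communities, while disconnected blobs can never be merged at any
resolution (Louvain only moves nodes between neighboring communities), so
a low resolution recovers contiguous tumors without under-segmentation
risk.  Resolution remains the main free parameter of the module.  Tumor
pseudobulks are scored for a program with the deviation machinery, tumors
as cells; high tumors are strictly above 1.5.

## The synthetic generators

All randomness descends from one integer seed through named spawn-key
streams, so any modality regenerates independently and byte-identically.
The generators and what they emulate:

- **Clonal scores** — clone random effects N(0, clone_sd) on heritable
  features plus condition mean shifts plus N(0, noise_sd) cell noise; an
  exceptional-memory subpopulation is planted by adding a high shift
  (default +3) to a chosen fraction of case-condition clones on the first
  heritable feature.  Defaults (50 clones, 20 cells/clone, noise SD 1)
  mirror the clone-size scale at which the heritability test is expected to
  operate.
- **Barcode reads** — one template-valid 48-mer per clone,
  rejection-sampled to pairwise edit distance > 8 so the distance-4
  collapse cannot merge distinct clones even in noisy data; reads are
  prefix + anchor + barcode with substitution errors at `error_rate`
  (substitution-only — no indel model is claimed for the sequencer; the
  parser's indel behaviour is exercised separately with constructed reads).
  Decoy reads are drawn from an A/C/G alphabet, which provably cannot
  contain a window within one mismatch of the T-rich anchor.
- **Counts** — per-cell depths lognormal(8.5, 0.35) (≈5,000 median counts),
  multinomial over gamma-distributed feature rates.  The multinomial is the
  Poisson rate model conditioned on the cell's total, which keeps the
  conservation invariant (column sums equal drawn depths) exact.
  Condition and high-subpopulation effects multiply the target family's
  rates.
- **Footprints** — shared baseline scores uniform on [0.25, 0.6] (above the
  exclusion threshold), planted +delta gains in the case condition at sites
  whose peak-level co-occurrence follows an explicit 2×2 design (default
  40/20/20/320, odds ratio 32), with paired sites at a fixed bp spacing.
- **Spatial sections** — a regular grid with circular tumor blobs at
  rejection-sampled well-separated centres; blob bins carry a 5× marker
  fold, and a configurable fraction of blobs carry a 3× fold on the program
  genes.

What the generators do *not* emulate: sequence content (GC, mappability),
fragment-level ATAC structure, doublets, batch effects, spatially smooth
background gradients, or irregular tumor shapes.  Recovery tests therefore
demonstrate the correctness and calibration of the algorithms under the
assumed generative structure, not robustness to artifacts real data may
carry.

## Problem sizes and numerical choices

Test and acceptance runs use: 1,000 cells × 500 features × 1,000
permutations for calibration/power; 2,000 cells / 40 clones for barcode
round-trips; 2,000 × 5,000 count matrices with 250 background sets for
deviation nulls; 400-peak footprint universes; 40×40–60×60 spatial grids
with 2–8 blobs.  These sizes give stable statistics in seconds per stage.
SDs use the n−1 denominator everywhere a choice exists (documented per
function).  Degenerate inputs (zero-SD features, empty groups, single
clones, uniform markers) are flagged or raised, never silently imputed.
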