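# Methods

This note documents the models implemented in `scontact`, their
assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Contact model and quality control

Contacts arrive as 4DN-style pairs records extended with a cell-barcode
column (and optionally a read-ID column grouping multi-way walks).
Positions are 1-based; records are normalised to the upper triangle of
the genome ordering, with ties broken by (chromosome order, position).
Binning is 0-based half-open: `bin = floor((pos − 1) / resolution)`,
and the global bin index concatenates chromosomes in file order — hg38
with chr1..chr22 + chrX tiles into 3,044 bins at 1 Mb.

Contacts are classified as trans (different chromosomes), cis-long
(same chromosome, distance strictly greater than 1 kb) or cis-short.
A cell passes QC when its total contact count strictly exceeds the
threshold (default 1,000); the threshold is per-library configurable
because adequate depth differs between preparations. QC is applied
before blacklist filtering, so the reported class counts describe the
library as sequenced.

## Copy-number inference

Copy number is inferred from coverage alone: per-bin **anchor counts**
(each contact deposits two anchors, so intra-bin self-ligations count
twice) are optionally rolling-median smoothed per chromosome, divided
by the genome-wide median over unmasked bins, and doubled under a
diploid assumption — `inferred copy = 2 × copy ratio`. Anchor counts
rather than diagonal-once marginals are used because a focally
amplified bin's contacts are dominated by intra-bin ligations; counting
them once deflates exactly the bins the callers care about (~30% in
simulation).

The smoothing window defaults to 1 (off). A median filter of width 5
erases single-bin amplifications entirely, and at the callers' 1 Mb
feature resolution a typical amplicon *is* a single bin; window ~5 is
appropriate for noisy pseudo-bulk profiles ahead of segmentation (the
CLI `cnv` command defaults to 5). Segmentation is a greedy changepoint
merge: a new segment opens when the copy level changes more than
1.5-fold against the running segment mean, and segments shorter than
`min_seg_bins` (default 3) are absorbed into their flank. It serves
reporting; the ecDNA features never depend on it.

Masked bins (blacklist, zero mappability) are excluded from the median
and reported as missing. The estimator assumes the cohort is
predominantly diploid; in a genome-wide aneuploid sample the median
normalisation shifts and all copies scale accordingly.

## Per-bin interaction metrics

* **Hub index**: Gini coefficient of the query bin's trans contacts
  aggregated per chromosome. The own chromosome and excluded
  chromosomes (default chrY) are dropped; chromosomes with zero
  contacts stay in the vector, since removing them would deflate the
  index. Computed on raw counts (not binarized contacts). An all-zero
  vector is undefined and propagates as NaN.
* **Trans-to-cis contacting-bin ratio** `R = N_T / N_C` with both
  partner-bin counts taken at the same resolution as the query bin;
  the bin itself counts as a cis partner when self-contacts exist.
  `N_C = 0` makes R undefined: such rows are excluded from model
  fitting and imputed at prediction time with the per-bin population
  median (falling back to the training medians), which avoids
  fabricating a ratio and is rare at realistic depth.

## Logistic caller

An unpenalised multivariate logistic regression on
(inferred copy, hub index, trans-to-cis ratio), binary
ecDNA-vs-not, thresholded at 0.5 by default (0.95 is a sensible strict
screen). Rows with undefined features are dropped from fitting.
`fit_lr` reports held-out sensitivity/specificity/precision/accuracy
from a stratified 80/20 split.

## Convolutional caller

Input per (cell, bin): the binarized 5 × B neighbourhood (rows = query
bin ± 2 at 1 Mb, columns = all B global bins, entry 1 iff any contact),
the 5 × 5 local block among the five neighbourhood bins (diagonal =
intra-bin contacts), the hub index of the centre bin from raw counts,
and L1-normalised row means of the binarized neighbourhood (all-zero
neighbourhoods get zero row means and hub index 0 so a genome-wide scan
never crashes; such rows are excluded from training).

Architecture: conv module 1 (8 channels, 5 × 45 kernel, stride 1, no
height padding so height 5 collapses to 1, width padding 22 for "same"
width) → batch norm → ReLU → max-pool (1, 2); dropout 0.5; conv module
2 (16 channels, 1 × 45, width padding 22) → batch norm → ReLU →
max-pool (1, 2); flatten (16 · B/4) and concatenate the 25 + 1 + 5 side
features; dense 223 → batch norm → GELU → dropout 0.5; dense 64 → GELU;
dense 3 → softmax. B is genome-derived, right-padded with zero columns
to a multiple of 4 so both pooling stages divide evenly; strides and
paddings are configurable since only the kernel/channel/pool sizes are
fixed by design.

Training: AdamW (lr 0.001, decoupled weight decay 0.001 on weight
matrices only), batch size 32, 40 epochs, a cell-level 90/10
train/validation split, and the hard bootstrapped cross-entropy
`L = −Σ_c (β t_c + (1−β) z_c) log p_c` with β = 0.99, where `t` is the
one-hot truth and `z` the one-hot argmax prediction (treated as
constant in the gradient); at β = 1 the loss is exactly cross-entropy.
Class weights default to inverse class frequency with the negative
("none") class additionally scaled by 2, so positive calls cost more —
raising the negative weight monotonically suppresses positive
predictions. Every random choice (initialisation, split, shuffling,
dropout) derives from one seed; training is bit-reproducible because
the whole network is numpy with hand-derived gradients (verified
against central differences in the test suite).

Scanning predicts every global bin except the first two and last two
(no height padding means the margin lacks a full neighbourhood), i.e.
B − 4 bins per cell; argmax ties resolve to the lowest class index
("none" wins). Validation metrics are reported at the (cell, bin) level
and, for the binary collapse, also at the cell level (a cell is
positive if any row is), since either convention is defensible.

## Trans-interaction significance

For an ecDNA locus, each trans chromosome is treated separately:
interval *i* (500 kb default) with `N_i` locus contacts is tested
against `X ~ Binomial(Σ_g N_g, E_i)` with `E_i = CN_i / Σ_g CN_g`,
upper tail `P(X ≥ N_i)`. The null says contact frequency follows copy
number alone. Bonferroni correction is applied across all emitted
intervals genome-wide (the conservative scope). Chromosomes without
locus contacts are skipped with a warning; intervals with zero copy but
nonzero contacts have `E_i` floored at 1e-6. The implementation matches
exact tail enumeration to 1e-12 relative tolerance for totals ≤ 1e4.

The hub-index shuffle null reassigns the chromosome label (not the
within-chromosome position) of every trans contact uniformly over
eligible chromosomes per cell — a multinomial redraw preserving
per-cell totals — and compares observed per-cell hub indices to their
null means with a one-sided Wilcoxon signed-rank test. Because real
trans contact mass scales with chromosome length while the null is
uniform, even evenly dispersed (ecDNA-like) loci sit above the null.

## Boundary refinement

At 10 kb within a 1 Mb candidate: per-bin local interaction sums
(contacts among candidate bins) → centred rolling mean (window 3) →
first differences → changepoints where |diff| exceeds the mean |diff|
over the region. The centred smoothing smears a sharp step across a run
of consecutive changepoints, so each boundary is taken at its run's
centre: the outermost rising run starts the interval, the outermost
falling run ends it. A profile with no changepoint above the cutoff is
returned unchanged and flagged. The mean-|diff| cutoff is one
operationalisation of an "average difference" rule and is configurable.

Genes are ecDNA genes only under strict body containment in the refined
interval; with two intervals, genes in both are shared and genes in
exactly one are 5′/3′ variable, sided by their midpoint against the
shared core (5′ = left of core in genome coordinates; strandedness is
not consulted). Copy-vs-expression coupling is the per-gene Spearman
correlation across cells between expression and mean gene-body inferred
copy; constant vectors are flagged undefined rather than given a value.

## Multi-way hubs

A read supports a multi-way contact if, after per-contact filtering
(trans or cis > 10 kb; blacklist pairs removed; autosomes only), it
still touches ≥ 3 unique 10 kb bins — filters first, then the unique
count. Per cell type, bin frequency = fraction of cells with the
indicator set (a bin counts once per cell regardless of read
multiplicity). Mean and SD are estimated over bins excluding the top 1%
by frequency (strict nearest-rank percentile) and mappability < 0.8,
then every bin gets `z = (f − mean)/SD`; a hub needs z > 1.96 and
adequate mappability. High frequency alone never disqualifies a bin —
the top-1% rule only keeps outliers out of the background estimate.

A caveat the tests make explicit: against a homogeneous binomial
background the z > 1.96 rule has an irreducible ~2.5–5% per-bin false
rate, so bin-level FDR ≤ 0.1 is only achievable when true hubs are a
sizable minority of bins (the planted-hub recovery runs use 10%); in a
sparse-hub regime the threshold controls recall, not FDR, and hub
calls should be read together with the enrichment tests. Enrichment
against annotation bin sets uses Fisher's exact test per (hub type,
annotation type) with the sample log2 odds ratio (Haldane–Anscombe 0.5
correction when any cell is zero); matched pairs are compared against
unmatched by rank tests.

## Domains

Boundary probability is positives / cells-of-type per 25 kb bin, over
externally supplied per-cell boundary calls. The variable-boundary test
builds an n-types × 2 table per bin, chi-square without continuity
correction, Benjamini–Hochberg FDR across tested bins, and calls a bin
variable iff FDR < 0.001 **and** max − min probability > 0.05 (the
difference gate keeps trivially significant but tiny effects out). Bins
with zero positives everywhere are skipped; bins with expected counts
below 5 are flagged.

## Annotation and cellular states

scGAD scores count raw contacts with at least one anchor bin in the
gene body at 10 kb (the anchor-either rule; intra-gene contacts count
once). Label transfer uses the k = 15 Euclidean nearest reference
neighbours with standardized scores `D_m = (1/(d_m+ε)) / Σ (1/(d+ε))`,
ε = 1e-8 — summing to one, strictly decreasing in distance — and
assigns the label with the highest aggregate score. Overlap validation
computes `O_ij = max_k min(|A_i∩C_k|/|A_i|, |B_j∩C_k|/|B_j|)` through
co-embedding clusters (the max-over-k-of-min reading of an ambiguous
printed formula; documented, not asserted as the only one). Embedding
construction itself (PCA/CCA/harmony) is out of scope; embeddings are
inputs.

State scores are signature mean minus expression-matched control mean
per cell, with controls drawn per signature gene from its
average-expression bin (30 bins, 100 controls per gene, seeded,
signature genes excluded from the pool). The projection is
`D = max(SC_OPC, SC_NPC) − max(SC_AC, SC_MES)`; within the winning pair
the identity value is `log2(|SC_a − SC_b| + 1)`, signed positive toward
OPC (progenitor pair) or AC (differentiated pair) — the sign convention
is a package choice. Hi-C cells inherit state scores as the
neighbour-weighted sum `HSC_j = Σ_g SC_j(g) · D_m(g)`, a convex
combination of the neighbours' scores.

## Synthetic data

The generator emulates barcoded droplet Hi-C libraries: per-cell depth
Poisson around 5,000 contacts (configurable, exact for conservation
tests); anchors drawn proportional to local DNA abundance (diploid
background plus per-cell Poisson-realised amplicon copies); cis
partners by a truncated power-law distance decay (density exponent 1);
trans partners with chromosome and position weighted by DNA abundance,
so amplified loci receive trans landings in proportion to their copies
— the assumption the binomial test encodes. ecDNA amplicons contact all
other chromosomes in proportion to size with a high trans rate (0.35)
and keep all cis-mapped contacts inside the amplicon (circular
geometry); HSR amplicons use a lower trans rate (0.15) with 85% of
trans mass on a 5 Mb target window, plus genuine flanking cis contacts.
The default toy genome is four chromosomes of 28/22/18/12 Mb (B = 80 at
1 Mb): unequal lengths matter, because they are what places even
ecDNA-like dispersion above the uniform chromosome-shuffle null, as in
a real karyotype. Multi-way walks and a matched negative-binomial
expression matrix (state shifts, linear copy dosage) complete the
cohort.

What the generator does **not** emulate: compartments, TADs and loops
beyond distance decay; restriction-fragment structure and ligation
artefacts; mappability variation; doublets and ambient contamination;
batch effects. Passing tests therefore demonstrate the estimators'
correctness and the direction/magnitude of the ecDNA–HSR contrasts
under controlled conditions, not performance on real libraries — the
near-perfect caller metrics on these cohorts are upper bounds set by
the cleanly separated generative classes.

## Problem sizes and numerical choices

The acceptance runs use 500 cells per class at depth 5,000 (~7.5 M
contacts), CNN training on 1,500 labelled (cell, bin) rows for 40
epochs, 20-draw shuffle and boundary replicates — sizes chosen so the
complete verification runs in minutes on a single CPU while keeping
every statistical check well-powered. Ties at argmax go to the lowest
class; Gini uses the sorted closed form; batch norm uses batch
statistics in training and running averages (momentum 0.1) at
evaluation; all-zero inputs are defined away rather than special-cased
downstream (zero row means, hub 0 in the scanner). Degenerate inputs
(empty vectors, single-class labels, all-zero coverage, k larger than
the reference) raise immediately with the offending name.

## Known limitations

* The copy estimator is coverage-ratio based and assumes diploidy; it
  has no GC/mappability covariate model and is not a substitute for a
  dedicated CNV caller on real data.
* The CNN trains per genome binning (B); transferring a model across
  genomes with different B requires retraining.
* Bin-level FDR of the multi-way z-threshold is uncontrolled in the
  sparse-hub regime (see above).
* Boundary refinement assumes one contiguous amplicon per candidate
  region; fragmented amplicons yield the outermost envelope.
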