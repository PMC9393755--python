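# Methods

`diffarch` compares the three-dimensional genome organisation of two
conditions from binned Hi-C contact matrices together with matched
chromatin-accessibility (ATAC) and expression (RNA) data. This note
describes the models and procedures each stage implements, the parameters
that matter, what the synthetic-data generator emulates, and the numerical
choices made where the design was genuinely open.

## Contact matrices and balancing

A contact matrix `M` for one chromosome holds symmetric, non-negative
interaction counts at a fixed bin width (working resolution 5–10 kb;
compartments at 100 kb). Intra-bin pairs are counted once on the diagonal,
so the upper-triangle mass equals the number of input pairs, and replicate
merging is element-wise addition.

Per-bin multiplicative biases (mappability, GC, restriction-site density)
are removed by iterative correction (ICE): the retained submatrix is
alternately divided by its normalised marginals until the coefficient of
variation of the marginals falls below `tol` (default 1e-5, `max_iter`
200), then rescaled to preserve the total mass. The estimated bias vector
`w` satisfies `corrected[i,j] = raw[i,j] / (w_i * w_j)` exactly and is kept
on the matrix for downstream use. Before correction, low-coverage bins are
masked: zero marginals, plus marginals more than `mad_filter` (default 3)
median absolute deviations *below* the median. The filter is deliberately
one-sided — its purpose is to remove bins the correction cannot rescue;
high marginals are precisely the multiplicative bias ICE removes, and a
symmetric filter would discard several percent of healthy bins whenever
biases are realistically log-normal.

Two-condition comparisons first scale both matrices to the smaller total
mass, then form `log2((b+pc)/(a+pc))` with pseudocount 1 raw-count
equivalent (avoids infinities at empty pixels).

## A/B compartments

At 100-kb resolution the observed/expected (O/E) matrix — counts divided by
the mean at each separation — is turned into a Pearson correlation matrix
across bin profiles; compartments are the sign pattern of its leading
eigenvector (PC1), computed by a deterministic symmetric
eigendecomposition. Positive PC1 = A (open), negative = B (closed), exact
zero or masked = NA. Because an eigenvector's global sign is arbitrary,
PC1 is oriented against an external reference track (ATAC coverage by
default): bins in the top quartile of reference signal must have positive
mean PC1. Chromosomes with fewer than 10 valid bins, or with a constant
O/E map, are rejected rather than returning meaningless signs.

Switch categories per bin are the label pairs A→A, B→B, A→B, B→A; genome
fractions are reported both over informative (non-NA) bins and over all
bins. DE-flagged genes are assigned to the category of the 100-kb bin
containing their (strand-aware, 1-bp) TSS; genes on NA bins are dropped
and tallied. Per category the package reports median/mean log2 fold
change, per-condition log2(FPKM+1) levels, and pairwise two-sided Wilcoxon
rank-sum tests.

## TAD-separation score and differential boundaries

For window sizes `w` derived from `minDepth=15 kb, maxDepth=75 kb,
step=7.5 kb` at 5-kb bins (floor(bp/res), duplicates removed — the set
{3,4,6,7,9,10,12,13,15} bins; the same bin set is used at 10 kb by scaling
the bp parameters with resolution), the diamond at bin *i* is the mean of
the inter-block submatrix between `(i-w, i]` and `(i, i+w]`, averaged over
valid cells only (a diamond needs ≥50% informative cells). Diamond means
are z-scored per window across the chromosome and averaged across windows;
lower scores mean stronger insulation. The score is defined only where
every window fits inside the chromosome.

Boundaries are local minima (flat runs resolve leftmost) that (a) lie at
least `delta` (default 0.01) below the lesser flanking local maximum and
(b) pass a one-sided rank-sum test of the O/E-normalised pixel values of
the largest-window diamond at the minimum against those pooled at the two
flanking maxima, with Benjamini–Hochberg correction across candidates at
q < 0.01. The test deliberately uses O/E pixels, not the per-window
diamond means: neighbouring window means are almost perfectly correlated,
so mean-level tests separate completely at every noise minimum, while raw
pixels span the whole distance-decay range and bury the insulation signal.

Differential classes: boundaries matched across conditions within
`match_tol_bins` (default 1) are **stable**; condition-2-only boundaries
whose ±1-bin-averaged condition-2 score is lower (more insulated) than
condition 1 at that bin are **gained**; condition-1-only boundaries with a
higher condition-2 score are **lost**; condition-specific boundaries
failing their score comparison are reported **unclassified**. The four
classes partition the boundary union exactly. TADs are the intervals
between consecutive boundaries (chromosome-end segments are not counted);
size distributions are compared by a two-sided rank-sum test.

## Loop detection and APA

Loop calling keeps the classic three-stage logic — strict candidate
selection, a negative-binomial count test, and a local rank-sum
confirmation — with the null expectation of pixel `(i,j)` anchored to its
*local* background: the mean O/E in the square ring between Chebyshev
radii `peak_width` (1) and `neighborhood_width` (5) around the pixel
(floored at 0.5), times the distance expectation, times the bias product
`w_i*w_j`. Structural elevation shared by a whole neighbourhood —
within-TAD or same-compartment blocks — is thereby part of the null, and
only focal enrichment counts. The count test runs on the raw-count scale:
testing ICE-corrected values directly inflates tails wherever biases are
small. Extra-Poisson dispersion is estimated per distance stratum by
method of moments (`Var(Y) = m + αm²`; strata under 20 pixels are pooled
with neighbours; α ≤ 0 falls back to a Poisson tail). Tail p-values are
computed for **every** tested pixel and BH-corrected over that whole
family — correcting only pre-selected candidates would void FDR control.
Calls require candidate status (≥`min_enrichment`=2 over the local null
and above the 0.95 stratum quantile), NB q < 0.05, and a one-sided
rank-sum p < 0.05 of the peak O/E against its ring; adjacent significant
pixels merge 8-connected, represented by the maximum-observed pixel.
Search range: ring-width to `maxLoopDistance` 1 Mb.

HOMER-style significant interactions are per-distance z-scores of observed
counts (z ≥ 1, normal tail p < 0.05, BH q reported) for separations
> 20 kb and ≤ 1 Mb.

APA stacks O/E submatrices of half-width `k`=10 bins around each loop
pixel (loops within `2k` bins of the diagonal or a chromosome edge are
skipped and tallied); the score is the centre pixel of the mean stack over
the mean of the k×k corner block at larger genomic distance.

## Enhancer–promoter interactions

An EPI is a loop with one 1-resolution anchor overlapping a gene's TSS and
the other overlapping at least one enhancer, at ≥1 bp under 0-based
half-open coordinates. Both role orientations are tested; a loop valid in
both directions yields both calls flagged ambiguous; the two roles must
sit on different anchors. EPIs inherit the loop's gained/lost/stable
class; differential tallies deduplicate genes and count DE-flagged genes
only. Expression direction between gained- and lost-EPI DEGs is a
two-sided rank-sum test on log2FC.

## Metaprofiles and flanking condensed regions

Metaprofiles average a bedGraph signal in fixed windows (±50 kb around
boundaries, ±100 kb around accessibility changes; 1-kb position bins)
around feature centres; features whose window leaves the chromosome are
excluded from the mean. Boundary profiles are centred on the insulating
bin *edge*, where the diamond geometry places the insulation point.
Gene-body profiles rescale each body to a fixed number of bins with
strand-aware fixed flanks.

The flank-dip detector looks, on each side of the profile centre, for the
widest contiguous run below `(1 − min_depth_frac)` × the side's baseline
(median of the outer third of that side; `min_depth_frac` default 0.25),
whose centre lies within `search_window` (default 30 kb) of the profile
centre; a dip is reported when the run is at least `min_width` (10 kb)
wide. The run's full extent is reported even when it reaches past the
search window — truncating at the window would clip every dip whose body
straddles it and bias widths low. Ratio thresholds make the detector
invariant to global scaling. Absence of dips is a valid report.

## The synthetic two-condition generator

The generator emulates the statistical structure this analysis assumes.
Expected counts factorise as

    mu[i,j] = depth · (|i−j|+1)^(−α) · plaid(i,j) · tad(i,j) · loop(i,j) · w_i · w_j

with α = 1, plaid = 1 ± 0.3 for same/cross-compartment bin pairs, a
cross-TAD factor 1 − insulation_depth (default 0.5, i.e. a 50% contact
reduction across boundaries), focal loop pixels multiplied by 5, and
log-normal biases (sd 0.3). Counts are Poisson draws (the loop caller's NB
machinery must therefore control error under a noise model it did not
assume — a robustness property, not a circular validation). Compartment
blocks are 0.5–1 Mb on the 100-kb grid; their edges are forced to coincide
with TAD boundaries, since compartment transitions in real genomes fall at
domain boundaries; TADs are 200–600 kb. Sequencing depth defaults to 1200
expected counts between adjacent 10-kb bins (~17M intra-chromosomal
contacts per 20-Mb chromosome), fixed by a power requirement: a 5× focal
peak at the maximum loop distance (1 Mb) must clear a genome-wide
FDR-corrected Poisson tail with ≥95% probability — the depth of a
deeply sequenced, merged-replicate in situ Hi-C library appropriate for
loop calling.

Condition 2 replants: 10 compartment switches per direction, 8 TAD splits
(gained boundaries) and 8 merges (lost), 25 loop gains and 25 losses over
40 shared loops, and 20 gained plus 20 lost EPIs (TSS placed in one anchor,
a 500-bp enhancer in the other). Split TADs must leave halves of ≥150 kb so
that the planted boundary is resolvable by the largest insulation window.
ATAC tracks carry higher signal in A than B compartments (1.4 vs 0.6 —
this also drives PC1 orientation), Gaussian peaks at boundaries (amplitude
2, sd 5 kb) and loop anchors (1, sd 3 kb), 20-kb condensed dips at ±25 kb
around every boundary at 40% depth, and 5% multiplicative noise.
Expression effects are N(±1.5, 0.5) log2FC for genes in switched blocks,
N(±1.0, 0.4) for EPI genes, N(0, 1) for DE genes in stable regions, and
N(0, 0.3) non-DE background. All draws derive from a single seed;
identical configurations produce byte-identical bundles.

What the generator does **not** emulate: polymer-physics contact
geometry, replicate variability, copy-number and translocation artefacts,
restriction-fragment granularity, trans-chromosomal contacts, and
sequence-level features (motifs, GC structure). Passing recovery tests on
this generator therefore demonstrates the pipeline's statistical
correctness under its assumed data-generating structure, not performance
on any particular real library.

## Analysis scales and test scenarios

Tests and the acceptance script run on a 2 × 20 Mb genome at 10-kb working
resolution (2,000 bins per chromosome) — large enough for ~45 TADs and
~60 loops per chromosome with minute-scale runtimes; the 5-kb scale used
on real data is supported throughout. The TAD-size direction check uses a
splits-only scenario (`n_tad_splits=-1`: every eligible TAD split once, no
merges), since the default balanced replanting leaves counts and sizes
matched by construction. The loop caller's null behaviour is measured on
pure decay + Poisson matrices.

## Known limitations

- Only intra-chromosomal matrices are modelled; whole-genome views are
  per-chromosome compositions.
- Loop anchors are single pixels after merging; extended stripe or dot
  clusters are represented by their maximum.
- The boundary test assumes enough informative diamond pixels; on very
  sparse matrices (far below the generator's depth) its power degrades
  before its error control does.
- `classify_boundaries` matches greedily by distance; pathological
  boundary clusters within the match tolerance could in principle match
  sub-optimally.
- The EPI module takes enhancer annotations as given and performs no
  enhancer prediction or activity weighting.
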