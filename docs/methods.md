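# Methods

This note records the models, parameter defaults and numerical choices
behind each stage of `gliakit`, and what the synthetic-data validation
does and does not establish.

## Single-cell pipeline

### Droplet pre-filter and QC metrics

Barcodes with fewer than 100 total UMIs are removed before anything
else; a barcode with exactly 100 is kept (the threshold is a floor, not
a strict bound). Per-cell metrics follow the usual definitions:
`nFeature_RNA` counts genes with nonzero UMIs, `nCount_RNA` the total,
`percent.mt` the percentage of UMIs on `mt-`-prefixed genes.
`nFeature_Y` / `nCount_Y` count detected Y-chromosome genes and their
UMIs; Y-linkage comes from the gene annotation table, not from name
patterns.

### Sex assignment

The classifier is a pair of mutually exclusive rules on raw counts
(male: Xist < 1 and nFeature_Y > 0; female: Xist > 0, nFeature_Y < 2,
nCount_Y < 2), applied before normalization — the thresholds of 1 and 2
are count-scaled and only make sense on raw UMIs. Because the rules are
mutually exclusive, evaluation order is immaterial; cells matching
neither are `undefined` and excluded. On clean singlets the call is
exact by construction of the rules; errors can only enter through
doublets (male+female collisions) or ambient Xist/Y molecules, which is
what the validation checks.

### Per-type QC gates

The gates use strict inequalities exactly as stated (a cell sitting on a
threshold is dropped). They are monotone: relaxing any threshold can
only keep more cells, which is asserted as a property test. Custom
thresholds can be supplied for types without built-in gates.

### Module scores

Genes are cut into 24 equal-frequency bins of mean log-normalized
expression; each set gene draws 100 control genes with replacement from
its bin, and the score of a cell is the mean expression of the set
minus the mean of the pooled controls. 24 bins / 100 controls are the
canonical defaults of this scoring scheme; both are parameters. Binning
and control draws use a canonical gene order (mean, then name) so
scores are invariant to the storage order of genes, and a fixed seed
makes them reproducible. Cell-cycle phase is the arg-max of the S and
G2M scores when positive, else G1; an exact positive tie resolves to S.
Gene lists (IEG, cell cycle, subtype signatures) are inputs (GMT),
not constants of the package.

### Normalization, embedding, clustering

Expression is depth-normalized to 10,000 counts and log-transformed
(natural log, pseudocount 1). The embedding selects 2,000 highly
variable genes by log-scale variance, centers and unit-scales them with
values capped at ±10, and decomposes by exact SVD; 17 PCs are the
top-level default, 16 for astrocyte/microglia subtype analyses. Before
subtype clustering the confounder genes (Sod1, Gm8566, Cmss1, Cdk8,
Xist, Gm42418, Gm424181, Malat1) can be excluded via
`pca_embed(exclude_genes=...)`; they are not removed from DE.

Clustering builds a k=20 nearest-neighbor graph in PC space, converts
it to shared-nearest-neighbor Jaccard weights (edges pruned below
1/15), and partitions by resolution-parameterized modularity
(Leiden-type optimization, seeded). Cluster labels are contiguous from
1, ordered by decreasing size. The package promises truth recovery
(ARI against planted labels), not partition identity with any specific
tool release.

### Markers, DE, fold changes

Markers are one-vs-rest Wilcoxon rank-sum tests reported when the gene
is expressed in ≥ 10 % of the cluster and its log2FC exceeds 0.25.
Differential expression between two cell groups uses Welch's t-test on
log-normalized values (Wilcoxon selectable), restricted to genes
detected in at least 3 cells of the union; zero-variance genes get
p = 1 and a `degenerate` flag rather than an undefined statistic. The
fold change is computed on the depth-normalized scale with a
pseudocount: log2FC = log2((mean(expm1 x_A)+1)/(mean(expm1 x_B)+1)) —
the scale on which the 0.25 and 1.0 thresholds were calibrated.
Multiple-testing correction is Bonferroni by default (BH by flag);
significance (p_adj < 0.05 and |log2FC| > 1) is a stored flag, never a
row filter.

### Pseudobulk

Pseudobulk sums raw counts over (condition, age, sex); column sums
equal the summed counts of the member cells exactly. For PCA the
columns are normalized to counts per million, log1p-transformed and
gene-centered; scores and loadings are both returned so that a
displaced sample can be traced to the genes loading the separating
component (the package's validation plants an end-stage effect and
checks that exactly those genes carry the extreme loadings).

### Cluster annotation and proportions

A cluster receives a type label only when every listed canonical marker
is expressed (nonzero) in at least 80 % of its cells; the per-marker
("each") rule is the default, an "any" rule is available by flag
because the informal phrase "expressing the markers" is ambiguous.
Clusters matching zero or several types are reported `ambiguous`, never
silently assigned. Proportion tables normalize within each stratum
(e.g. condition), so a condition-exclusive state shows a 0 fraction in
the other condition.

## Preranked GSEA

The enrichment score is the weighted Kolmogorov–Smirnov running sum
with weight p = 1 (p = 0 selectable): along the ranked list, hits add
|r_j|^p normalized over hits, misses add 1/(N − N_H), and ES is the
signed maximum deviation. Ties in the ranking metric break by gene name
so the list — and hence every ES — is deterministic; the extremum is
found from the 2·N_H candidate values at and just before each hit,
which is exact and O(N_H) per evaluation.

The null is gene-label permutation (preranked mode): hit positions are
redrawn uniformly per set, n_perm = 1000 by default. For a fixed
ranking this null depends only on the set size, so permutations are
shared across equal-sized sets — statistically identical to per-set
permutation and much faster for large collections.
p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign
nulls), never zero; NES = ES / mean(|same-sign null ES|); sets with no
same-sign nulls report the 1/(1 + n_perm) bound with a flag and no
NES. Sets are kept when their intersection with the universe has 10 to
800 genes; BH adjusts across retained sets, and `relevant` additionally
requires a leading edge of more than one gene, so single-gene-driven
calls are excluded.

A consequence worth knowing: with 1000 permutations the smallest
attainable p is about 2/1000, so after BH adjustment across hundreds of
sets no set can reach p_adj < 0.05. That is a property of
permutation-resolution, not of the implementation; validating planted
detection therefore uses a small collection, and calibration uses the
raw p-values.

## Histology quantifications

### Yen threshold

The threshold maximizes Yen's maximum-correlation criterion over the
255 cut points of a 256-bin histogram, computed in closed form from
cumulative first and second moments. It equals exhaustive maximization
by construction (asserted against an independent per-cut evaluation and
against a second implementation of the same criterion). Foreground is
`value > threshold`. Integrated density "limited to the threshold" is
interpreted as the sum of strictly suprathreshold intensities per
image, averaged over images per animal; the thresholds used are
recorded in the output.

### Sholl profiles

Profiles are measured on binary masks of maximum projections. Circles
start at 5 µm from the soma center and step by 5 µm; each circle is
sampled at arc steps of at most 0.5 px and an intersection is one
maximal contiguous run of foreground along the circularly-closed sample
sequence — a process of any width crossing the circle counts once, and
the run wrapping the angular seam is merged. Two deliberate choices:

- single-sample gaps (< 1 px of arc) are closed before counting,
  because a binary mask cannot represent a background corridor narrower
  than one pixel — such gaps are rounding flicker at a process
  boundary, and without this rule exactness against the geometric
  oracle fails on a few percent of noiseless trees;
- radii whose circle leaves the image are reported as missing (NaN),
  never as zero, so truncated cells do not fake reduced branching.

The soma center is supplied or taken as the centroid of the largest
foreground component. Coordinates are physical µm at the interface and
pixel indices (origin at the corner, y down) internally.

### Volume fraction and brightest substack

Frames are ranked by mean intensity; the top 20 are kept in original z
order, with exact ties resolved to the lower z index. Each selected
frame is auto-thresholded individually — the per-frame mask method is a
genuinely free choice here, so Otsu is the default, Yen is selectable,
and the method used is recorded in the output — and the volume fraction
is the mean covered fraction of the per-frame masks. Constant frames
contribute 1 if uniformly bright and 0 if blank, flagged.

### Co-localization counts

Nuclei are segmented from the smoothed (σ = 1 µm), auto-thresholded
maximum projection of the DAPI channel; connected components are kept
within area bounds scaled from a nominal 10-µm nucleus (0.1–4× the
nominal disk area). A nucleus is positive for a marker when its mean
intensity in the marker's maximum projection exceeds that channel's
threshold; a marker channel with no signal at all yields zero
positives. Ratios (e.g. CC3+APC+ / APC+) are computed from co-positive
counts and reported with the raw counts.

## Synthetic data

The count simulator emulates the structure the pipeline assumes: a
2 conditions × 4 ages × 2 sexes design (one sample per cell of the
design), three glial types at their observed relative abundances
(astrocytes 0.28, microglia 0.42, oligodendrocytes 0.30), a 3.9 %
doublet formation rate, an ambient fraction of 1.5 % (the middle of the
1–2 % range such experiments report), lognormal library sizes (median
5,000 UMIs, σ = 0.35 — consistent with the QC gate windows), a mean
mitochondrial fraction of 3 %, and a shared negative-binomial
dispersion θ = 2. Counts are gamma-Poisson draws from per-group
expression profiles; doublets copy the summed pre-ambient counts of two
recorded singlet parents; ambient counts are Poisson draws from the
dataset-mean profile at the ambient fraction of each barcode's library
size. Sequencing depth and dispersion are free parameters, not
calibrated to any deposited dataset.

Two realism decisions matter for interpretation:

- besides its few canonical markers, each cell type (and each planted
  subpopulation) carries a broad expression program — 100 genes at 4×
  (40 at 4× for subpopulations) — because real cell types differ in
  hundreds of genes and no clustering can separate types that differ in
  three. Program sizes and folds are fixed defaults of the generator;
- genes with a planted role (markers, effect genes, program genes) have
  controlled baseline abundances rather than lognormal draws, so their
  detectability is by construction, not by luck of the draw.

Planted defaults mirror the biology of this disease model: a 30-gene
end-stage
(4 M) response in SOD1 microglia at log2 effect 2; a
disease-associated microglial state (Apoe/Cst7/Lpl/Itgax) present only
in SOD1 samples; and a stress-response astrocyte state (Cdkn1a/Fkbp5)
confined to 3 M control males. Sex structure plants Xist only in female
and Y genes only in male singlet profiles, so cross-signal in a clean
singlet is impossible and every classifier error is attributable to
doublets or ambient molecules.

The image simulators are built for analytic ground truth: nuclei are
disks, fibers constant-width segments, microglia are radial polyline
trees. The tree generator constrains geometry — monotone radius growth,
bounded angular drift, branch joints and tips nudged away from sampling
radii, soma radius (3.5 µm) below the first sampling radius — so the
analytic crossing count provably equals mask-run counting on a
noiseless render. Fiber frames accumulate segments until the mask
reaches the target fraction, recording the exact pixel fraction as
truth; frame brightness varies so brightest-frame selection is
exercised. None of the image simulators model a PSF, optical sectioning
or depth attenuation.

**What passing validation shows — and does not.** Recovery on these
simulations demonstrates that the implementations compute what they
claim (rules applied exactly, statistics matching oracles, planted
effects recovered at the stated operating points). It does not
demonstrate robustness to what the simulators omit: batch effects and
sample integration, empty-droplet ambiguity, cell-type-dependent
depth, optical blur, uneven staining, or touching nuclei. Those belong
to the tools this package deliberately leaves out of scope
(integration, doublet detection, ambient correction, deconvolution).

## Problem sizes used in validation

The shipped validation scenarios are sized for a desk run (about half a
minute for the full acceptance script, under a minute for the test
suite): 10,000 cells for the sex classifier, 200 cells per group × 20
replicates for DE, 500 random sets × 1000 permutations for GSEA
calibration, 10 random trees for Sholl, 100 histograms for Yen, four
planted fiber truths, three nuclei fields, and 3,200 cells for
subpopulation recovery — the last chosen because a ~60-cell planted
state must comfortably exceed the k = 20 neighborhood size of the
clustering graph to be separable at all.
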