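# Methods

This package re-implements, as a tested pipeline over synthetic data with
known ground truth, the quantitative analyses used to compare
simultaneously-born (isochronic) cortical neurons across corticogenesis:
laminar-dispersion statistics of birthdated imaging cohorts, single-cell
count-matrix QC and radial expression tables, a permutation-based
molecular-heterogeneity statistic, and downstream clustering and marker
analyses.

## Imaging cohorts and laminar dispersion (`ftquant`)

**Gating.** Directly progenitor-born neurons carry a bright FlashTag (FT)
pulse label and no chronic BrdU (they underwent no intercurrent S phase).
Per section, `gate_direct_born` keeps cells with FT intensity strictly
above the section median and BrdU intensity strictly below the section's
20th percentile. Percentiles use linear interpolation between order
statistics everywhere in the package. The alternative top-10%-FT gate
(`gate_top_ft`) keeps cells at or above the (1 − fraction) FT quantile,
with boundary ties kept. The BrdU cut is read as a percentile of all
detected cells of that section, and the FT median is computed on all
detected cells before any other filtering; both choices are conventions,
stated here rather than inferred.

**Radial position.** Depth is normalized between the subplate lower border
(0) and the pial surface (1) as r = d_sub / (d_sub + d_pia), where the two
distances are nearest-point Euclidean distances to the manually traced
landmark polylines. The nearest-point ratio (rather than a normal
projection) is well defined for curved landmarks and makes r invariant
under rigid motions of the section; cells whose distance sum exceeds the
local band thickness by more than 10% are flagged and excluded from
cohorts. Cortical-plate (CP) mode rescales so the CP lower/upper landmark
polylines map to 0/1; the band ends are summarised as the mean
cortex-depth of each CP polyline's vertices, and rescaled positions
outside [0, 1] are excluded and counted.

**Dispersion and comparisons.** Cohort spread is summarised by the sample
SD (n − 1 denominator), the IQR, and the mean-normalized IQR. Cohort
distribution shapes are compared by agglomerative clustering (average
linkage, Euclidean metric — the linkage is a convention exposed as a
parameter) of density histograms of mean-centered positions, 20 bins over
[−0.5, 0.5]; centering removes cohort location so the clustering responds
to spread and shape only, and the flat cut at k = 2 mirrors the
early-broad vs late-compact contrast. Early vs late dispersion groups are
compared with Welch's unequal-variance t-test on per-cohort SDs, raw
position distributions with the two-sample two-sided Kolmogorov–Smirnov
test, and dispersion time courses with per-label OLS of SD on collection
day, reporting the slope's 95% CI and the mean-response band (the "linear
integration with 95% band" convention).

Degenerate inputs: a section with all-equal FT intensities keeps no cells
(warned); two constant, equal dispersion groups return t = 0, p = 1 by
convention; a trend with a single distinct day is rejected.

## Count-matrix QC and normalization (`scqc`)

The in-memory container is `anndata.AnnData` (cells × genes, raw integer
counts); on disk, Matrix Market (genes × cells) plus `genes.tsv` /
`cells.tsv`. Mitochondrial genes come from an explicit `mito` flag column
or, failing that, the `mt-` name prefix.

Cell QC drops cells with fewer than `min_genes` detected genes (default
2000) **or** more than `max_mito` mitochondrial read fraction (default
12%). Both comparisons are strict, so a cell at exactly the threshold is
kept; the OR reading is used because either condition alone marks a
low-quality cell. Cells with zero total counts are dropped and flagged
separately. The gene filter keeps genes with ≥ 100 counts in ≥ 2 cells
(defaults). Normalization is reads-per-million with a log2(x + 1)
transform; the pseudocount of 1 is a convention exposed as a parameter.
Radial expression tables min–max normalize each gene's log2 values to
[0, 1] across cells; constant genes map to all-zero and are flagged.

## The heterogeneity ratio (`hetero`)

Within-condition molecular heterogeneity is quantified as the ratio of
variance explained by PC1 in actual vs gene-permuted data, under repeated
subsampling:

1. draw `n_cells` = 80 cells without replacement;
2. rank genes on the subsample's raw counts by vst-style standardized
   variance and keep the top `k_genes` = 80;
3. compute the PC1 variance fraction λ₁/Σλ of the per-gene centered and
   unit-scaled log2(RPM+1) submatrix;
4. independently permute each gene across the 80 cells (exactly
   preserving per-gene marginals) and recompute;
5. record the ratio; repeat for `n_reps` = 100 cross-validations.

A ratio near 1 means gene–gene covariance is indistinguishable from
chance; latent subtype structure pushes it above 1. All 100 per-rep ratios
are kept (the distribution, not a single summary, is the result). Per-rep
seeds are fanned out from the master seed with a counter-based
`SeedSequence` spawn, so any rep is reproducible in isolation.

The vst ranking fits a local quadratic regression of log10(variance) on
log10(mean) (tricube weights, span 0.3 — the named method's published
defaults) over genes with nonzero mean and variance, standardizes each
cell's value by the fitted SD, clips at √n_cells, and ranks by the
variance of the clipped values with deterministic ties by gene id. Genes
are re-selected within each subsample by default (matching the stated
order: cells selected, then genes identified); a `genes_per_rep=False`
switch selects once per condition instead. Unit scaling before PCA is a
flag (default on, matching the standard scale-then-PCA convention); both
settings are tested against an SVD oracle.

The epoch contrast (early E12–E13 vs late E14–E15, per stage) is a thin
contract over standard statistics: a paired t-test on per-rep epoch means,
reported as F(1, n_reps − 1) = t²; unbalanced rep counts fall back to a
Welch contrast with a warning. The adult deep- vs superficial-layer
contrast is a two-sided Mann–Whitney on the per-rep ratios.

## Clustering and markers (`progclust`)

Newborn-neuron clustering follows the conventional graph recipe: top
variable genes (vst ranking), PCA to 15 components on scaled log2(RPM+1),
a k = 20 nearest-neighbour graph with Jaccard-weighted shared-
nearest-neighbour edges (pruned below 1/15), and Leiden modularity
communities at resolution 1.0, deterministic given the seed. The variable
gene count should be read proportionally: 2000 genes against a
genome-wide matrix corresponds to roughly the top 10–15% of genes on the
reduced synthetic panels.

Cluster markers are ranked one-vs-rest by log2 fold change of mean
log2(RPM+1) after a two-sided rank-sum screen with Benjamini–Hochberg
correction (the test choice is a convention). The early-variable-gene set
takes the top 50 variable genes of two birthdate rankings and
deduplicates genes present in both, so its size is always
2·50 − overlap; with an overlap of 11 this yields 89 genes, the only
reading consistent with that printed arithmetic (discarding both copies
would give 78). Late-marker thresholds are the mean RPM of each marker
over cells of designated late-born reference clusters (default: the
clusters with the largest E14+E15 fraction); positive fractions are
computed only among cells with marker RPM > 0 (a dropout guard), with the
numerator strictly above the threshold.

## Synthetic data (`synthgen`)

**Imaging.** A cohort is one section with jittered pia and subplate
landmark polylines; true depths are Normal(center, spread_sd) clamped to
[0, 1] (clamping, not resampling — a small boundary mass appears for
extreme specs) and mapped to pixel coordinates between the landmarks.
Intensities are log-normal (nonnegative, right-skewed, like imaging
intensities): direct-born cells (default 15% of cells, a minority as in
the labelling design) draw FT from the bright mode and BrdU from the dark
mode, diluted cells the reverse.

**Expression.** Baseline per-gene means are gamma-distributed
(shape 0.6, scale 150 — deep full-length single-cell libraries, so that a
realistic share of genes clears the 100-count gene filter) and drawn once,
shared across conditions. Counts are negative-binomial via
gamma–Poisson with size θ = 2 (biological CV ≈ 0.7), with independent
Bernoulli dropout (default 10%) — dropout independent of expression level
is the simplest model sufficient to exercise the "> 0 RPM" guard. Each
condition plants k disjoint subtype programs of 40 genes shifted by
2^effect_logfc; conditions can share a `program_group` so cells of
adjacent birthdates draw from the same molecular types. The first
⌈2%·G⌉ genes are flagged mitochondrial. Optional depth-gradient genes
(laminar-marker analogues) scale their mean with the cell's recorded
radial position and use a tighter NB size (20), since graded laminar
markers are strongly position-determined in real data.

The default condition panel mirrors the study design: birthdates E12–E15
at stages AP / N1d / N4d plus adult deep-layer (3 subtypes, logfc 2) and
superficial-layer (1 subtype) conditions; early N1d conditions carry the
strongest latent structure (3 shared subtypes, logfc 2), early AP
conditions weak structure (2 subtypes, logfc 0.8), late and N4d
conditions none — encoding the transient post-birth surge of
heterogeneity in early-born neurons.

Random streams are structured so that two specs differing only in one
condition's effect size produce bit-identical counts for every non-program
gene (scale-free standard-gamma draws; one Poisson child stream per gene).
Effect-size ladders are therefore paired by construction, which the
monotonicity check exploits: it fixes the gene selection per condition
(`genes_per_rep=False`) and uses 400 cross-validations so the smallest
ladder step (logfc 0 → 0.5, about +0.005 in mean ratio) is resolved above
Monte-Carlo noise.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no batch effects, doublets or ambient RNA; no
expression-dependent dropout; no gene–gene correlation beyond the planted
programs; imaging landmarks are near-horizontal jittered polylines, not
curved anatomy; intensity modes are cleanly separated, so gate recovery
rates on real, overlapping intensity distributions will be lower.

## Problem sizes and numerics

Default analysis runs use ~1000-gene, 120-cells-per-condition panels and
cohorts of 150–400 cells; these sizes keep the full pipeline and test
suite fast while leaving every statistic well inside its asymptotic
regime (the heterogeneity procedure's 80-cell/80-gene core is the stated
design and is independent of panel size). Quantiles interpolate linearly;
hierarchical clustering uses average linkage; PCA uses full SVD; a 1e-12
ridge guards rank-deficient local-regression windows; near-tie gene ranks
break deterministically by gene id. Known limitations: the CP-band
summary assumes roughly parallel CP landmarks; the Welch fallback for
unbalanced heterogeneity designs ignores the repeated-measures pairing;
and the clustering contract fixes K only through the resolution
parameter, not directly.
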