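# Methods

## Scope and data model

The package analyzes paired single-cell and spot-based spatial
transcriptomics of a two-arm cohort (responder / non-responder, e.g. T-cell
expanded vs non-expanded, or pCR vs non-pCR).  It consumes precomputed
cluster and region labels: embedding, graph clustering, batch integration,
doublet and ambient-RNA removal are deliberately out of scope.  Counts are
held in a validated `CountMatrix` (observations × genes, non-negative
integers, unique IDs, metadata covering exactly the observations); one
spatial sample is a `CountMatrix` plus planar spot coordinates and a region
label per spot.  Coordinates are abstract planar units — no image
registration — so all distances are relative.

## Quality control and normalization

Cells with total counts below `min_counts` (default 1,000) or mitochondrial
fraction above `max_mito` (default 0.15) are removed; equality is kept on
both boundaries ("fewer than" / "exceeding" read literally).  Samples whose
surviving cell count falls below `min_cells_per_sample` (default 1,000) are
then dropped whole.  The filter is idempotent.  Normalization is
ln(1 + scale·count/total) with scale 10⁴; zero-total cells stay all-zero
with a warning rather than erroring, since they are legitimate in sparse
spot data.

## Marker detection

One-vs-rest per cluster: genes are gated at fraction-expressing ≥ 0.1 in
the cluster and log₂ fold change ≥ 0.25, where the fold change is computed
on mean expm1 of the normalized values with a 1e-9 pseudocount (the
convention of the widely used single-cell marker tools).  Gated genes get a
two-sided Wilcoxon rank-sum p-value: exact by full enumeration of
assignments (midranks, so ties are handled) when the pooled size is ≤ 10,
otherwise the tie- and continuity-corrected normal approximation,
vectorized across genes.  BH correction is applied over all reported tests;
within a cluster rows are ordered by ascending q then descending log₂FC.
No p-value return threshold is applied — downstream consumers decide — so
a fully separated 3-vs-3 toy gene is reported with its exact p of 0.1.

Gene-set signature scores (e.g. a 30-gene co-expression-module signature
used as a subtype marker panel) are the mean normalized expression over the
set genes present in the matrix; absent genes are dropped with a warning.

## MIA niche annotation

For cell type *T* and spatial cluster *R*, the top markers of each (up to
`top_n`, best by q then log₂FC) are intersected within a declared gene
universe; the overlap k follows a hypergeometric distribution under
independence.  Both tails include P(X = k), so p_enrich + p_deplete ≥ 1.
The signed score is −log₁₀ p_enrich when enrichment is the smaller tail,
+log₁₀ p_deplete otherwise (negative = depletion); p floored at 1e-300.

Choices made where the method is conventionally underspecified:

- `top_n` defaults to 100, following the original MIA practice, and is
  configurable.
- The universe should be the intersection of genes tested in both
  modalities — the only choice making both sets subsets of the universe.
- An optional `max_q` filter (0.05 in the pipeline configuration, off at
  the library level) restricts both tables to significant markers first.
  Without it, clusters with few true markers are padded to `top_n` with
  noise genes that merely pass the fraction/fold gates, which dilutes the
  sets and deflates enrichment on small panels.
- No multiple-testing correction across the matrix: the scores are used
  descriptively for annotation; raw p matrices are exported alongside.
- Niche naming is an ordered rule list (`name`, `required_types`,
  `min_score` defaulting to 1.3 ≈ p < 0.05): first matching rule wins, so
  compound rules (e.g. an interface requiring both a stromal and an immune
  type) must precede the single-type rules they subsume.  Unmatched
  clusters are labeled `unassigned`.

## Spatial statistics

**KNN graph.**  Euclidean K-nearest neighbors per spot, self excluded,
K = 6 by default (mirroring a hex-grid neighborhood; the definition is
geometry-agnostic).  Distance ties are broken by ascending spot index so
graphs are bit-reproducible; duplicate coordinates are allowed.

**Proximity enrichment.**  Observed directed neighbor-pair counts per
region-label pair against a null of `n_perms` (default 1,000) label
permutations with a mandatory seed; z = (obs − mean)/sd with z = 0 where
sd = 0, symmetrized by averaging.  Because the null permutes positions,
the z matrix is exactly equivariant under renaming of labels.

**Radial distance.**  Signed nearest-member distance to a target region:
+d(spot, nearest member) outside, −d(spot, nearest non-member) inside, so
the sign flips exactly at the membership boundary.  Nearest-member (rather
than centroid or graph-hop) distance is the assumption recorded for this
implementation.  The stored display value is sign(d)·√|d|; the raw distance
is kept alongside.  Distance–expression profiles bin the transformed axis
into `n_bins` equal-width bins (mean, count, normal 95% CI per gene and
bin; bins with < 3 spots reported missing).

## Colocalization

Signals are depth-normalized counts: count/total × median(total), averaged
over the genes of a multi-gene signal.  Log transforms are deliberately
avoided because the score multiplies magnitudes.  The per-spot score is

    s_i = max( a_i · max_{j∈N(i)} b_j ,  b_i · max_{j∈N(i)} a_j )

with the neighbor maximum excluding the spot itself.  Extreme values are
winsorized at the `trim_q` = 0.99 quantile (capped, not dropped — spot
count is preserved).  "High-expression" masks take the ceil(0.10·n) largest
signal values with ties at the threshold broken by ascending index, and the
mask overlap is reported with its Jaccard index, the independence
expectation n·f_a·f_b, and a hypergeometric enrichment p over the spot
universe.

A caveat the test suite documents explicitly: on null data the high masks
of two *unrelated* genes still co-occur slightly above the independence
expectation, because spot-level depth noise is shared between genes and
total-count normalization cannot remove it completely (the total is itself
a noisy depth estimate).  The closed-form expectation is recovered once the
cross-gene coupling is broken by permuting one signal across spots.

## Cohort statistics

Per-sample subtype proportions (optionally within a parent compartment,
e.g. a macrophage subtype within myeloid cells) are compared between the
two arms with a two-sided rank-sum test — exact by enumeration for pooled
n ≤ 20 samples, asymptotic with tie correction beyond.  Subtype odds ratios
are computed on pooled cells (the convention for subtype-abundance
heatmaps; per-sample proportions are reported alongside so
pseudoreplication stays visible): OR = (a·d)/(b·c) on the type-vs-rest ×
arm-vs-arm table, Haldane–Anscombe +0.5 applied only when a zero cell
occurs, Woolf 95% CI, and a two-sided Fisher exact p on the uncorrected
counts.  Groups enter in sorted order; swapping the arms inverts every OR
and leaves p unchanged.  No correction across subtypes by default.

## Synthetic cohorts

The generator plants everything the pipeline is later asked to recover.

- **Cell types and markers.**  Five named types (epithelial, fibroblast,
  tcell, lpcaf, lam) with disjoint 10-gene marker blocks at
  `marker_fold` = 8 over `base_mean` = 5; counts are negative-binomial with
  size `dispersion` = 2 (variance μ + μ²/2), matching scRNA-seq
  overdispersion; per-cell lognormal depth factors (σ = 0.3) and
  Beta(2, 25) mitochondrial fractions exercise QC.  Marker folds are
  mean-preserving — a type's non-marker genes are down-scaled so every type
  has the same expected total counts.  This keeps sequencing depth
  independent of composition; without it, library-size normalization makes
  unrelated genes co-vary through the shared denominator and the
  colocalization null is confounded.
- **Spatial sample.**  A `grid_side`² lattice split by radius into a core
  (dominated by the epithelial-like type), an interface ring, and outer
  stroma (dominated by the fibroblast-like type).  Spots are mixtures of
  2–5 cells drawn from the region's composition.  On the interface ring the
  configured partner pair is planted in adjacent lattice positions as a
  checkerboard of A-dominant ({A: 0.65, B: 0.15}) and B-dominant
  ({B: 0.45, A: 0.25}) spots.  The asymmetry is intentional: it gives the
  interface a strictly dominant type (A ≈ 0.46 vs B ≈ 0.29 on average), so
  "does MIA's argmax recover the dominant type of every region" is a
  well-posed question.  In the planted-recovery checks MIA is run with
  `top_n` equal to the planted `markers_per_type`, matching the scale of
  the planted marker structure; with much larger `top_n` both partners'
  saturated 10-gene sets tie exactly and the argmax is undefined.
- **Cohort arms.**  Two arms ("E"/"NE") × `n_samples_per_group` samples ×
  `n_cells_per_sample` cells; the NE arm's odds for the enriched type
  (default lam) are multiplied by `enrichment_or` = 3, so the pooled-cell
  odds ratio has the planted expectation.
- **Null mode.**  The same lattice with uniformly random region labels and
  every spot an even mixture of all types — the negative control for
  proximity and colocalization.
- Identical config + seed is bit-identical; a seed is mandatory.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond cell-type structure, realistic gene
numbers, hexagonal spot geometry, or tissue morphology.  Passing the
planted-truth tests therefore shows the chain is correct and calibrated on
data satisfying its assumptions, not that it is robust to the artifacts of
real cohorts.

## Problem sizes and defaults in the checks

The test and acceptance runs use reduced study conditions chosen to keep a
single simulation under a second while preserving structure: 120 genes,
5 × 10 planted markers, 300 cells/sample, 2 samples/arm, 16 × 16 lattice.
Planted odds-ratio recovery runs at the full cohort scale that matters for
that statistic (10 samples/arm × 1,000 cells, 60 genes).  Calibration uses
1,000 null replicates for the rank-sum type-I rate (10 samples/arm,
Beta(2, 8) proportions) and 20 seeds × 1,000 permutations for the
neighborhood z-scores.  The demonstration pipeline config scales QC
thresholds to the simulated depth (e.g. `min_counts` 500 at 150 genes); the
library defaults keep the real-data values (1,000 counts, 15% mito, 1,000
cells/sample).

## Known limitations

- MIA annotates clusters, not spots; no deconvolution is performed.
- The rank-sum asymptotic branch is used per-gene at scale; exactness is
  only guaranteed for the small-sample branch (and verified against
  enumeration there).
- Winsorization level (0.99) and the high-expression decile are
  conventions, configurable but not data-adaptive.
- Odds ratios on pooled cells ignore patient-level clustering; the
  per-sample proportion tests are the guarded companion analysis.
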