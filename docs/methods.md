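# Methods

This note records the models and procedures c3map implements, the
defaults and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the design decisions that were
genuinely open.

## Normalization and differential expression

Count matrices are library-size normalized to a common total of 10,000
(CP10K) and transformed with natural log(1 + x). The common total and
log base are conventions; all downstream rank-based statistics are
invariant to them. A `lognorm` flag on the matrix prevents accidental
double normalization, and raw counts are retained in a `counts` layer so
QC metrics (mito fraction, totals) always use raw counts.

The differential-expression "score" is the two-sided Wilcoxon rank-sum
z statistic of one group against the rest of its scope, with the exact
tie-corrected variance
n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]. No continuity correction is
applied (the statistic is used chiefly for ranking; the test suite checks
agreement with scipy's asymptotic Mann-Whitney test without continuity
correction and with scanpy's tie-corrected implementation). Log2 fold
changes are computed on expm1-ed group means with a 1e-9 pseudocount —
the convention of the major single-cell toolkits — and p-values are
Benjamini-Hochberg adjusted within each group's gene list. Groups
smaller than 3 cells are excluded with a warning.

Subtype signatures take each group's top 200 genes by positive score;
a gene appearing in several top lists is assigned to the group with the
higher score, without backfilling, so signatures within a compartment are
disjoint and may be shorter than 200.

## Co-expression modules

Genes are filtered by differential expression (BH FDR ≤ 0.05 and
|log2 FC| ≥ 0.3, the fold-change filter being optional for spot data)
and then by connectivity: at least 5 partners at |Pearson r| ≥ 0.4 on
the normalized matrix. Survivors are clustered hierarchically on their
correlation profiles (Euclidean distance, complete linkage). The cut is
open in the source method, so it is exposed: either a requested module
count or, by default, the cut among 2–10 modules maximizing the mean
silhouette. Complete linkage was chosen because it yields compact,
balanced modules on correlation profiles; silhouette is a standard
internal criterion when no module count is prescribed.

One caveat worth knowing: library-size normalization induces weak
negative correlations between unrelated genes when a few programs
dominate the library. The degree filter (≥ 5 partners at |r| ≥ 0.4)
absorbs this in realistic settings, but on tiny simulated matrices
without a stable "background library" it can pull independent genes into
the graph; the tests therefore include high-count filler genes when
planting block structure.

## Gene-set scoring

Per-cell scores use the binned-background approach (signature mean minus
the mean of control genes drawn from matching average-expression bins;
25 bins, 50 controls per signature gene), delegated to scanpy's
`score_genes` with a fixed seed.

Per-sample ssGSEA follows the rank-weighted running-sum definition: with
genes ranked 1..N within a sample and weight exponent 0.25, the score is
Σᵢ [P_in(i) − P_out(i)] over the descending-expression walk, where P_in
weights in-set genes by rank^0.25 and P_out is the uniform ECDF of
out-of-set genes. Scores are optionally normalized by the global score
range, matching the reference implementation (the test suite checks
equality of enrichment scores against gseapy). The statistic depends on
the expression vector only through ranks, hence is invariant to monotone
transforms. Quartile stratification ranks samples (stable order on ties)
and splits them into four equal groups; constant scores collapse to Q1
with a warning.

## Latent-time transfer

Normal-epithelium cohorts carry a latent time t ∈ [0, 1] per cell (an
input, e.g. from an RNA-velocity model). Per sample, genes are ranked by
Pearson correlation of normalized expression with t and the top 500 with
r ≥ 0.3 are kept; the per-sample lists are unioned without duplicates.
The correlation is signed by default — a literal reading of "minimum
correlation" — with an absolute-value option, since down-regulated genes
are equally informative in principle.

Each tumor cell then inherits the latent time of the normal cell
minimizing the L1 distance of normalized expression over the shared
subset of that gene list (missing genes are dropped with a logged
count). Ties break to the lowest normal-cell index, making the transfer
deterministic; inherited times are, by construction, within the normal
cohort's observed range. Interval signatures bin tumor cells into 5
equal-width bins over the observed time range (last bin right-closed)
and reuse the 1-vs-all DE machinery with the same higher-score
tie-breaking.

## Ligand-receptor interactions

Receptor activity of cell c for receptor r is the mean over r's
signature genes g of |x(c,g) − μ_bg(g)|, where μ_bg is the gene's mean
over all cells of c's broad compartment. Activities are computed on
log-normalized expression with a pooled (cross-sample) background by
default; both choices were open and are configurable in spirit — the
deviation is well defined on any scale, and pooling matches the pooled
enrichment analysis downstream. Receptors whose prior signature has
fewer than 5 genes are excluded up front. Signature lists come directly
from the prior table; assembling them by walking a signaling graph is an
upstream curation step outside this package's scope.

Calls: ligands need log2 FC ≥ 0.5 (inclusive), BH p ≤ 0.05 and
expression in ≥ 10% of sender cells against the same-broad-type
background; receptor activities need log2 FC ≥ 0.25 (on the raw activity
means, since activities are not log counts) with the receptor gene
expressed in ≥ 10% of receivers. The spatial filter keeps a pair if in
at least one spot sample ≥ 25% (inclusive) of ligand-positive spots
(UMI > 0) are also receptor-positive. Interaction potential is the
product of mean sender ligand expression and mean receiver receptor
activity; display transparency is min(0.9, 1 − (potential/potential_max)²)
with potential_max taken over the records rendered together, so the
strongest ribbon is opaque and none vanishes.

## Hexagonal-grid topology

Spot arrays use integer array coordinates (x, y) with constant x + y
parity. Ring k around a reference is the six printed axial offsets
(x±(k+1), y±(k+1)) and (x, y±(k+2)); at k = 0 these are the six
immediate neighbors in the orientation where (x, y±2) is a neighbor.
For odd k the (x, y±(k+2)) offsets leave the parity lattice; they are
reported as missing rather than silently skipped, and an optional
full-ring mode returns the complete 6(k+1)-position hexagonal ring
(computed in axial coordinates q = (y−x)/2, r = x) for users who want
isotropic rings. Ring means use only positions present on the grid —
edge references average over fewer spots, never zero-filled — and
per-module profiles are z-scored across modules for display.

Reference spots are those at or above the 95th percentile of the module
score (ties included). The concurrence test forms a 2×2 table of
(top 5% vs bottom 5% of module score) × (gene expression above vs below
its own 95th percentile) and applies a one-sided Fisher exact test for
enrichment. Its p-value is discrete and conservative at these stratum
sizes, so under a null it is super-uniform: the calibration guarantee is
on type-I error (≤ 5% nominal), not exact uniformity of p.

## Imaging features, cell typing and niches

Membrane masks are nuclear masks dilated up to a radius with contested
pixels assigned to the nearest nucleus (scikit-image's label expansion),
so labels stay disjoint. Ring percentage examines the band just outside
each nuclear contour (default width 3 px, configurable; the width is not
prescribed by the source method) and reports the percent of pixels with
intensity strictly greater than 20.

Typing: declarative conjunctive gates build a training set (cells
matching several class gates are ambiguous and dropped); classes are
capped at 2,500 training cells by uniform subsampling; a kNN classifier
with 200 neighbors, uniform weights and Euclidean distance on
robust-scaled features (median/IQR fitted on training cells) assigns
labels, with ties resolved to the lexicographically first label. T-cell
subsets use k = 100 by passing `k` explicitly. Unresolved cells go
through 10 rescue rounds, each sampling up to 500 cells per subtype and
voting with k = 20; the majority label across rounds wins, and cells
rescued into immune subtypes are rejected rather than relabeled.

Neighborhood profiles take, within each core, the up-to-10 nearest cells
within distance 200 (raw image coordinates) plus the reference cell, and
record the broad-type composition; fewer neighbors are used near sparse
edges rather than reaching past the distance cap. Niches are k-means
clusters (k-means++ with 10 restarts, fixed seed) of these profiles. To
guide k, for each candidate the cells are split half/half at random and
a 1-vs-all L2-penalized logistic classifier per cluster is scored by
holdout AUC (rank-based); the mean AUC curve stays high up to the number
of genuinely distinct niches and declines as clusters start splitting
noise. Niche labels join the top positive-coefficient broad types of the
same classifiers. An explicit merge interface unions a named pair (or
all pairs above a centroid-correlation threshold), recomputing centroids
as member-weighted means — which niches to merge is a judgment call on
real data and is therefore never automated away.

Diversity is the Shannon entropy S = −Σ P(xᵢ) ln P(xᵢ) of the subtype
frequencies over a niche's unique member cells (natural log; S ∈
[0, ln n]). Note the entropy of a merged niche obeys the concavity bound
S_union ≥ weighted mean of the parts — it can fall below the more
diverse part when a large pure niche absorbs a small mixed one, which is
the mathematically correct behavior. Subtype enrichment per niche is a
two-sided Fisher test on (in niche) × (is subtype); marker enrichment is
a two-sided Mann-Whitney test of a marker on one subtype inside vs
outside a niche (skipped below 3 cells per side); proximity is the
per-spot median distance from each query cell to its nearest target cell
(a cell is never its own nearest target), compared across query subtypes
by Mann-Whitney over spot-level medians, with spots required to hold at
least 25 cells of every type examined.

## Synthetic data: what it emulates and what it does not

All generators draw UMI counts from a negative-binomial (gamma-Poisson)
law, counts ~ NB(mean μ, var μ + μ²/φ) with dispersion φ = 2 by default
— the standard overdispersion model for UMI data. Per-gene baseline
means are log-normal (σ = 0.6) around 1; per-cell depth varies
log-normally. Defaults define the study conditions:

- Tumor cohort: 5 subtypes × 200 cells, 600 genes, 10 planted markers
  per subtype at log2 FC 2 (base mean 2 so the effect is measurable above
  NB noise), 10 "MT-" genes attracting 1–8% of UMIs per cell, and an HTO
  table with 4 hashtags, ~85% singlets, 5% doublets, 5% true negatives
  and 5% recoverable negatives (one hashtag above threshold but initially
  called negative).
- Normal cohort: 500 cells with latent time uniform on [0, 1]; 50 time
  genes whose NB mean rises log-linearly with t (log2 FC 3 across the
  axis, base mean 3). The effect size is set so the realized per-gene
  Pearson correlation with t on normalized data is ≈ 0.45–0.5: library
  normalization partially cancels a trend shared by many genes, so the
  planted per-gene effect must exceed the target correlation.
- Spot grid: 30 × 30 hexagonal array (900 spots) with valid-parity
  coordinates; a contiguous disk covering ~4% of the grid (so it nests
  inside a top-5% score stratum) carries 10 module genes and 5 companion
  genes at log2 FC 3; spot totals are log-uniform on [800, 4000],
  spanning the 1,250-UMI QC boundary. Mutually exclusive gene pairs can
  be planted to exercise the spatial co-expression filter's negative
  case.
- Imaging cores: 5,000 cells over 4 cores of 1,000 × 1,000 image units;
  each core's quadrants are planted niche regions with four distinct
  broad-type mixtures (tumor-dominant, immune, stromal, mixed tumor/T);
  one defining marker per broad type is elevated 8-fold on that type, and
  a "CD49a" channel is shifted by +3 on CD8T cells inside the mixed
  niche. Quadrants (500 units) are large relative to the neighborhood
  radius (200), so most profiled cells are interior. A separate image
  generator paints disk nuclei with known ring positivity for the
  ring-percentage tests.
- Ligand-receptor prior: 30 pairs, 10% of receptors with < 5 signature
  genes to exercise the exclusion rule.

The generators plant structure; they do not emulate batch effects,
ambient RNA, doublet expression profiles, segmentation errors, imaging
noise physics, spatially varying cell density, or read-level data.
Passing tests therefore demonstrate that the procedures recover the
structures they target under the assumed noise model, not robustness to
every artifact of real assays.

## Numerical and interface choices

- Determinism: every stochastic step takes a seed; generators derive
  independent streams from a base seed, so equal seeds give
  byte-identical outputs.
- QC tie policy: cells exactly at a percentile boundary are retained
  (minimal-removal reading of "top and bottom 5%"); mito filtering
  precedes the percentile filters, which are applied jointly to the
  surviving set. Applying a QC filter to an already-filtered object is a
  recorded no-op, which is what makes the filters idempotent (percentile
  trimming re-applied naively would keep shaving tails).
- Boundary semantics follow the stated thresholds exactly: > 10% mito
  removed (10.0% retained), ≥ 1,250 UMIs kept, ≥ 4 spots kept, ≥ 5
  signature genes kept, fold-change and co-expression thresholds
  inclusive, intensity "> 20" strict.
- Degenerate inputs warn rather than fail where a sensible result
  exists (constant scores, empty bins, no surviving genes) and raise
  where none does (empty matrices, empty priors, disjoint gene lists).
- Problem sizes in the test and acceptance runs (≤ 1,000 cells, ≤ 900
  spots, 5,000 imaging cells, 20–40 null replicates) were chosen as the
  smallest instances at which the planted effects are comfortably
  detectable and brute-force oracles remain exact.

## Known limitations

- The rank-sum z uses the normal approximation throughout; for groups of
  a handful of cells an exact permutation test would differ.
- Receptor-activity backgrounds are pooled across samples; strong
  inter-sample composition differences would argue for per-sample
  backgrounds.
- The printed axial ring formula samples 6 positions per ring (and 2 of
  them leave the lattice for odd k); the full-ring mode exists precisely
  because those profiles are anisotropic.
- k-means niches assume roughly spherical profile clusters; rare niches
  smaller than k-means' resolution are absorbed into neighbors and only
  recoverable by raising k and merging.
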