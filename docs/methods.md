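# Methods

This note documents the models, parameter choices and numerical details
behind `degentraj`, and what the synthetic validation does and does not
establish about real data.

## The analysis model

The pipeline treats retinal degeneration as a continuous process sampled
cross-sectionally: at any one age, cells of the degenerating type occupy
different positions along a shared molecular trajectory. The analysis
therefore (i) separates discrete cell populations by unsupervised
clustering, (ii) orders the degenerating population along a one-dimensional
principal curve ("pseudotime"), and (iii) characterizes how each gene's
expression moves along that axis.

### QC and normalization

Cells are kept with 200–6000 detected genes and 1000–20,000 transcripts
(both bounds inclusive; boundary inclusivity is a convention we fix and
test), after removing genes seen in fewer than 3 cells. Gene filtering runs
first and cell metrics are recomputed afterwards, which makes the combined
filter idempotent. The mitochondrial fraction uses the `mt-` symbol prefix
(13 protein-coding mitochondrial genes in mouse). Normalization is
ln(1 + 10⁴·count/total): natural log throughout (the base is a convention;
only ratios of back-transformed values matter downstream).

Variable genes use the classic mean/dispersion method: per-gene mean and
variance-to-mean ratio of expm1(normalized values), dispersions z-scored
within 20 equal-frequency mean bins, selection window mean ∈ [0.1, 8] and
standardized dispersion > 1, capped at the 5000 most dispersed (window
first, cap second). Scaling regresses each gene on total UMI by per-gene
OLS on the normalized scale, standardizes residuals to mean 0/variance 1,
and clips at ±10; genes whose residuals are numerically constant scale to
exactly 0.

### Clustering and doublets

PCA retains 50 components (sign-fixed so each component's
largest-magnitude loading is positive, making runs comparable). The SNN
graph connects cells by the Jaccard overlap of their k = 20 nearest-neighbor
sets (each cell a member of its own set), pruning weights ≤ 1/15. Community
detection is Louvain modularity optimization with resolution scaling of the
null term (γ = 0.8), run through igraph with an explicitly seeded RNG; the
reported modularity is recomputed from the definition on the returned
partition rather than taken from the optimizer.

Doublet removal implements the marker-co-expression idea at the level of
cluster *types*: clusters whose mean expression profiles (Spearman over the
variable genes) correlate ≥ 0.8 are merged by connected components before
marker ranking. This matters because the stages of a degenerating cell type
form several clusters that share their defining markers — at cluster
granularity none of them has any specific marker, and doublets falling into
a partner's cluster would be invisible. Power markers per type are ranked
by cluster-vs-rest AUC (≥ 0.8) with detection outside the type ≤ 20 %, top
10 per type; a cell expressing ≥ 3 markers of at least one foreign type is
flagged. The flagging thresholds (3 markers, 1 foreign type) are
configurable; with the defaults the synthetic scenario yields doublet
sensitivity ≈ 0.99 at a false-flag rate ≈ 0.015.

### Pseudotime

The trajectory subset (clusters selected by the expression of a
user-supplied trajectory marker gene; start cluster = the one richest in
wild-type cells when genotype annotation is available) is re-processed:
fresh variable genes (top 3000), scaling, and PCA to 12 dimensions.
Cluster centroids are joined by a Euclidean minimum spanning tree and the
path from the start cluster to its farthest tip (cumulative distance)
initializes the curve.

The principal curve is fitted by the Hastie–Stuetzle alternation: project
cells onto the current polyline (exact point-to-segment projection,
arc-length positions), then smooth every PC coordinate against arc length.
The smoother is a running local average over an index window of 10 % of the
cells, evaluated at 100 rank positions — a scatterplot smoother in the
original principal-curve spirit, chosen over a smoothing spline because it
is O(n), exactly deterministic, and free of knot-placement artifacts on
strongly non-uniform pseudotime densities. Convergence is declared when the
mean squared projection distance changes by < 1e-4 (relative), with a cap
of 50 iterations (non-convergence returns the best fit with a warning; in
practice the fit oscillates within noise at that point). Pseudotime is
oriented so the start cluster has the smallest median.

The final cluster lineage order is the ordering of cluster medians along
the fitted curve. The MST path is only the initialization: when one stage
protrudes orthogonally (e.g. a transient gene program peaking mid-course),
centroid-MST topology can become a near-tie star that skips the middle
cluster, while the curve itself still orders the cells correctly.

### Binning, patterns, DE, association

Cells are split into 20 equal-width bins over the pseudotime range
(equal-width, not equal-count, so bin occupancy reflects density); a
left-to-right sweep merges any bin with < 100 cells into its right neighbor
(the last bin merges leftward), restarting until stable. The per-gene bin
profiles of the DE-gene union are z-scaled across bins with the population
standard deviation and clustered by seeded k-means++ (k = 4, n_init = 10,
row-order independent). Centroids are labeled by shape rules applied in
order: *down* (starts at its maximum, first-third mean above last-third
mean), *early transient up* (argmax in the first half, final bin < 0.5·max),
*early permanent up* (≥ half the total rise reached by the midpoint and
final bin ≥ 0.5·max), *late up* (argmax in the last third), with a
correlation-to-template fallback. The 1/3, 1/2 and 0.5·max thresholds
operationalize qualitative pattern descriptions and are configurable.

Differential expression between pseudotime-adjacent clusters uses the
two-sided Wilcoxon rank-sum test: exact enumeration when both groups have
≤ 25 cells and the data are tie-free, otherwise the tie-corrected normal
approximation. avg_logFC = ln(mean(expm1 x_A)+1) − ln(mean(expm1 x_B)+1)
(natural log, pseudocount on group means). Genes are pre-filtered to
detection ≥ 10 % in at least one group and |logFC| ≥ 0.25; the Bonferroni
denominator is the number of genes actually tested after this pre-filter —
this is a reporting convention, and both filters are disabled (set to 0)
when measuring type-I error, since conditioning the null on the observed
fold change would bias the estimate. Hemoglobin-prefix genes can be
excluded from reported tables.

The association test regresses each gene's normalized expression on a cubic
B-spline basis of pseudotime (6 degrees of freedom, knots at pseudotime
quantiles) and performs a Wald F-test of the joint nullity of the spline
coefficients under a Gaussian working model. With ~2000 cells the CLT makes
the F-test well calibrated on log-normalized counts (measured type-I error
0.04–0.05 at α = 0.05); a negative-binomial GAM would be the heavier
alternative and is noted as an extension point. Constant genes get p = 1 by
convention.

### Enrichment and similarity

Promoter windows are −2000:+500 around the TSS (sequences are supplied
pre-extracted, strand-aware). IUPAC consensus motifs are matched exactly
under degeneracy on both strands; N in a sequence never matches. PWMs are
scored as log-odds against a uniform background with a small pseudocount,
and a window is a hit at ≥ 80 % of the motif's maximum score (an artifact
threshold, configurable). Enrichment per motif is the one-sided Fisher
exact (hypergeometric tail) p, BH-adjusted across motifs; the z-score is
the deviation of the motif's p-value rank from its mean rank over 200
seeded random gene lists of the same size, scaled by the rank standard
deviation; the combined score is c = −ln(p)·z, signed so that larger c
means stronger enrichment. The background gene universe is an explicit
required input.

Cross-group similarity is Spearman's correlation (average-rank ties) of
per-group mean normalized expression over the 5000 most variable genes of
the main analysis; groups are cluster × genotype with ≥ 50 cells. qPCR
relative expression is 2^−ΔΔCt with replicate Ct values averaged per
(sample, gene) before ΔCt; significance testing on the resulting values is
left to any standard statistics package.

## The synthetic-data generator

Counts are negative binomial with mean s_c·b_g·f_g(t_c) and dispersion
θ = 2 (variance μ + μ²/θ), sampled as gamma–Poisson. Per-cell size factors
are lognormal (σ = 0.3, mean-normalized). The default scenario has 2000
genes and ~3900 cells in five populations: rods (2400, carrying the
trajectory), wild-type and mutant cones (250 each, sharing one cell-type
identity), Müller glia (400) and bipolar cells (300).

* **Trajectory.** Rod pseudotime is a three-stage mixture of reflected
  normals centered at t = 0.12/0.50/0.88 (sd 0.07) — the degenerating type
  presents as three discrete-ish clusters strung along one axis, matching
  how such data actually cluster. Stage 1 is wild-type, stages 2–3 mutant.
* **Pattern genes.** 50 genes per class with base means log-uniform on
  [0.25, 1]: multiplicative programs 2^(±δ·shape(t)) with δ = 2 (max |log2
  FC|): a decreasing sigmoid (midpoint 0.5), an early sigmoid (0.35), a
  Gaussian bump at 0.4 (sd 0.13) and a late sigmoid (0.75); steepnesses
  10–14. Midpoints are design choices for qualitatively described shapes.
* **Markers.** 20 genes per population, base mean 0.03 outside and 100-fold
  enriched inside (≈ 3 counts/cell) — the near-zero background expression
  typical of strong cell-identity markers (cf. rhodopsin), and what makes
  marker-co-expression doublet flagging specific.
* **Identity programs.** Populations of the same cell type share lognormal
  per-gene baseline factors (σ = 0.4) on background and pattern genes, so
  cell types differ transcriptome-wide, not just in markers; without this,
  between-type correlations are uninformatively high.
* **Mitochondria.** 13 `mt-` genes at base mean 8 (~5 % of counts).
* **Artifacts.** Doublets sum two random cells of different populations,
  binomially thinned to 1.3× the median singlet depth (capture saturation).
  Low-quality cells are copies of singlets whose non-mitochondrial counts
  are thinned by a factor in [0.05, 0.2] with mitochondrial counts
  preserved — the leaky-cytoplasm signature; most fall below the 1000-UMI
  floor and are removed by QC.
* **Coupling.** Optionally one population adopts the pattern-gene program
  at a fixed trajectory position (default t = 0.85) raised to a coupling
  power (default 0.9): mutant cones mounting nearly the full
  late-degeneration stress program, which is what makes them correlate more
  with late rods than wild-type cones do with wild-type rods.

What the generator does **not** emulate: ambient RNA, batch effects,
gene–gene correlation beyond the planted programs, UMI saturation, zero
inflation beyond NB sampling, or realistic gene-length/GC biases. Passing
the recovery tests therefore shows the pipeline's logic is correct and its
statistics calibrated under the stated model — not that any particular
biological dataset will yield the same accuracy.

## Problem sizes and determinism

The validation scenario (~3900 cells × 2000 genes) runs end-to-end in
roughly ten seconds on one CPU; the calibration simulations use 400–2000
cells and 500–2000 null genes, sizes at which the measured error rates are
stable to ±0.01. All randomness flows from one global seed fanned out
per stage through a SHA-256 hash of the stage name (so changing one stage's
seed usage cannot perturb another); two runs with the same configuration
and seed produce byte-identical output tables. Pipeline stages are cached
by a hash of their parameters chained with their upstream stage's hash, so
editing one parameter re-executes exactly that stage and its dependents.

## Known limitations

* Single-lineage trajectories only; no branching, no velocity.
* The Gaussian working model of the association test can be conservative
  for very sparsely detected genes (< ~5 % detection).
* Louvain on SNN graphs can split large continua at arbitrary internal
  boundaries; recovery scores against discrete-stage truth should be read
  with that in mind.
* The enrichment z-score depends on the chosen background universe; no
  default universe is shipped.
* Clustering label order, not identity, is stabilized across runs;
  comparisons across different configurations must match labels by content.
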