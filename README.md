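# degentraj

Single-cell analysis of progressive photoreceptor degeneration: a reusable,
tested implementation of the full trajectory pipeline used to study rod
death in the *rd10* retinitis-pigmentosa mouse model — from raw 10x-style
count matrices to degeneration pseudotime, pseudotemporal expression-pattern
classes, and promoter motif enrichment. It is aimed at computational
biologists who want the analysis logic of such a study as a library with
ground-truthed validation, rather than as a one-off collection of notebook
calls.

## What it computes

Given a sparse gene×cell count matrix (MatrixMarket + features/barcodes
TSVs), the pipeline runs:

1. **QC** — drop genes expressed in < 3 cells; keep cells with 200–6000
   detected genes and 1000–20,000 transcripts (inclusive); per-cell
   mitochondrial fraction from `mt-` genes.
2. **Normalization** — x<sub>gc</sub> = ln(1 + 10⁴·c<sub>gc</sub>/Σ<sub>g</sub>c<sub>gc</sub>);
   variable genes by the mean/dispersion window (mean of expm1(x) in
   [0.1, 8], binned-standardized dispersion > 1, top 5000); per-gene scaling
   to mean 0/variance 1 after OLS regression on total UMI.
3. **Clustering** — PCA (50 PCs), shared-nearest-neighbor graph (Jaccard
   overlap of kNN sets, k = 20, pruned at 1/15), Louvain modularity
   optimization at resolution 0.8.
4. **Doublet removal** — clusters are merged into cell *types* by
   transcriptome correlation; each type's power markers are ranked by
   cluster-vs-rest AUC (AUC ≥ 0.8, detected outside in ≤ 20 % of cells); a
   cell expressing ≥ 3 markers of a foreign type is flagged and removed.
5. **Pseudotime** — a Hastie–Stuetzle principal curve over the trajectory
   clusters (re-selected variable genes and PCA on the subset), initialized
   from the centroid minimum-spanning-tree path anchored at the start
   cluster; pseudotime is arc length along the converged curve.
6. **Binning and patterns** — 20 equal-width pseudotime bins, adjacent bins
   with < 100 cells merged; per-bin mean expression of the DE-gene union,
   z-scaled per gene, clustered by k-means (k = 4) and labeled
   *down / early permanent up / early transient up / late up* by shape rules.
7. **Differential expression** — two-sided Wilcoxon rank-sum between
   clusters adjacent in pseudotime; avg_logFC = ln(mean(expm1 x)+1)
   difference; Bonferroni over tested genes; report at adjusted p < 0.05,
   |logFC| > 0.25.
8. **Pseudotime association** — per-gene Wald F-test of a cubic B-spline
   regression of expression on pseudotime, Bonferroni-adjusted.
9. **Motif enrichment** — promoter windows (−2000:+500 around the TSS)
   scanned for IUPAC consensus or PWM motifs on both strands; per-motif
   one-sided Fisher exact p, Benjamini–Hochberg adjustment, rank-deviation
   z from random gene lists, combined score c = −ln(p)·z.
10. **Cross-genotype similarity** — Spearman correlation of per-group mean
    expression over the 5000 most variable genes; plus 2^−ΔΔCt relative
    expression for qPCR validation tables.

Every stage is validated against a bundled **synthetic-data generator** that
plants known ground truth: negative-binomial counts
(var = μ + μ²/θ), multiple cell types across two genotypes, one population
carrying a continuous degeneration trajectory with four pseudotemporal gene
programs, injected doublets and damaged low-quality cells.

## Worked example

```python
from degentraj.config import PipelineConfig
from degentraj.pipeline import run_pipeline

cfg = PipelineConfig(out_dir="run", seed=1,
                     synthetic={"doublet_rate": 0.05, "lowq_rate": 0.03,
                                "coupled_population": "cone_rd10"})
res = run_pipeline(cfg)
print(res.manifest["stages"]["trajectory"])
print(res.pattern_assignment.centroid_labels)
```

prints (seed 1):

```
{'status': 'computed', 'trajectory_clusters': [0, 1, 2], 'lineage': [0, 2, 1],
 'start_cluster': 0, 'n_cells': 2349, 'n_bins': 18, 'converged': True, ...}
['down', 'early_transient_up', 'early_permanent_up', 'late_up']
```

i.e. the three rod clusters are ordered wild-type → early → late along the
fitted curve (cluster 0 has the highest wild-type fraction and anchors the
lineage), the ~2350 trajectory cells fall into 18 merged pseudotime bins,
and the four k-means centroids of the binned DE genes map onto the four
canonical degeneration patterns. Scored against the generator's ground
truth this run recovers the stage clustering with ARI 0.91, pseudotime with
Spearman ρ 0.93, and assigns 100 % of the planted pattern genes to their
true class.

The same stages are available from the shell:

```bash
degentraj simulate --out sim/ --seed 1
degentraj run --in sim/ --out run/ --seed 1
degentraj qpcr --ct ct.tsv --ref Actb --calibrator wt_P21
degentraj enrich --genes de.txt --background bg.txt \
    --promoters promoters.fa --motifs motifs.meme
```

Reruns into the same output directory reuse cached stages; changing one
parameter (say `--resolution`) re-executes exactly the clustering stage and
its dependents, as recorded in `run/manifest.json`.

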