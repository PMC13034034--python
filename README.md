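# trichoflow

Single-nucleus RNA-seq analysis of leaf trichome development, as a tested,
reusable Python pipeline. It targets the study design in which two leaf
protoplast samples (CL-1, CL-2) and one trichome-enriched nucleus sample
(CT) are profiled to resolve the epidermal lineages of a tea leaf — the
epidermis → transitional-cell → trichome differentiation axis with its
guard-cell branch — without requiring access to the original sequencing
data: a bundled generator produces ground-truthed synthetic experiments
with the same statistical structure, so every stage is testable as a
recovery problem.

## What the pipeline does

1. **Cell calling** — barcodes ranked by total UMI count; with expected
   cell count *N*, *m* is the UMI count at the 99th percentile of the
   top-*N* barcodes and every barcode with at least 0.1·*m* UMIs is kept.
2. **QC and normalization** — cells kept with 200–8000 detected genes and
   < 50 000 UMIs; expression normalized as x′ = ln(1 + 10⁴·x/total);
   binned-dispersion HVG selection; PCA on the standardized HVG matrix
   (log library size regressed out).
3. **Batch correction** — iterative soft k-means: cells are softly
   assigned to clusters with a diversity penalty that down-weights
   clusters over-representing a batch; each cell then moves by the
   responsibility-weighted difference between its cluster's global
   centroid and its own batch's centroid, until the centroids stabilize.
4. **Clustering** — shared-nearest-neighbor graph (Jaccard weights,
   pruned < 1/15) partitioned with Leiden.
5. **Markers** — one-vs-rest Wilcoxon rank-sum per cluster; a gene passes
   with log2FC ≥ 0.36 (fold ≥ 1.28 on the de-logged scale), P ≤ 0.01 and
   expression in ≥ 25% of the cluster.
6. **Annotation** — reference-species markers transferred through a
   homology table (e-value ≤ 1e-5, best hit); each (cluster, type) scored
   S = 0.20·m₁ + 0.50·m₂ + 0.30·m₃ (marker quantity, fold magnitude,
   expressing proportion, each mapped to [0, 1]); highest score wins.
7. **Cell cycle** — binned-control module score per phase (G1/S/G2/M);
   highest-scoring phase assigned, cells below 0.3 on all phases are
   non-cycling.
8. **Transitional clusters** — clusters with CL/CT cell ratio in
   [0.5, 2.0] whose cells co-express the epidermal and trichome programs.
9. **Trajectory** — the epidermis/transitional/trichome/guard subset is
   re-embedded on its ordering genes, denoised, summarized by k-means
   landmarks and ordered along a minimum spanning tree rooted at the
   epidermis cluster; the branch point splits cells into three states,
   gene trends are clustered into early/transient/late modules and
   branch-dependent genes ranked by a two-branch rank-sum contrast.

## Worked example

```python
import numpy as np
import trichoflow as tf
from sklearn.metrics import adjusted_rand_score

sim = tf.simulate_experiment(tf.SimConfig(seed=0))   # 3 samples, ground truth
cells = sim.counts.subset_cells(sim.truth.is_cell)
filtered, report = tf.filter_cells(cells)
norm = tf.normalize_log1p(filtered.counts)
hvg = tf.select_variable_genes(norm, filtered.genes)
emb = tf.pca_embed(norm, filtered.genes, hvg, k=30, seed=0,
                   covariates=np.log(filtered.umi_per_cell()))
corrected, _ = tf.soft_kmeans_correct(emb.coords, filtered.sample_labels, seed=0)
labels = tf.cluster_cells(corrected, seed=0).labels
print(tf.batch_mixing_entropy(emb.coords, filtered.sample_labels),
      tf.batch_mixing_entropy(corrected, filtered.sample_labels))
print(labels.max() + 1, adjusted_rand_score(sim.truth.type_label[sim.truth.is_cell], labels))
```

prints (seed 0):

```
0.0 1.0195804795688261
5 0.8783954425117704
```

Before correction the three samples are completely unmixed (kNN batch
entropy 0.0); afterwards the entropy is near its maximum ln 3 ≈ 1.10, and
clustering recovers the simulated cell types (ARI 0.88, 5 clusters). The
`examples/` directory has one short script per capability — cell calling,
clustering, annotation, cell cycle, trajectory, and the on-disk/CLI
interface (`trichoflow simulate` / `run-all`).

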