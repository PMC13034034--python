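# Methods

This note documents the models and procedures implemented in trichoflow,
the defaults that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
capture about real single-nucleus data.

## Cell calling

Barcodes are ranked by descending total UMI count (ties broken by barcode
lexicographic order). With an expected cell count *N*, the robust maximum
*m* is the count at the nearest-rank 99th percentile of the top-*N*
slice, i.e. at position max(1, ⌈0.01·N⌉) from the top. Every barcode in
the **full** profile with count ≥ 0.10·*m* is retained (strictly smaller
counts are filtered), so barcodes ranked below *N* can be rescued. The
comparison is ≥ because the rule filters what is *less than* the
threshold. An `extra_barcodes` hook accepts an externally computed rescue
list (e.g. from an ambient-profile model); no ambient model is
implemented here. Degenerate inputs: *N* larger than the profile is
clamped with a warning; an all-zero top slice retains nothing.

## QC and normalization

Cells pass QC with 200–8000 detected genes (count > 0) and a UMI total
strictly below 50 000. The alternative gene bounds 310–6000 reported for
the same study design can be selected through the config; both are
supported, neither asserted as correct. Normalization is
x′ = ln(1 + 10⁴·x/total). Variable genes are ranked by within-mean-bin
z-scored variance (20 equal-frequency bins; ties break by gene ID;
zero-variance genes are never selected).

PCA standardizes each variable gene (clip ±10) and, by default,
regresses the log library size out of every gene first
(`regress_depth`). This guard exists because log-CP10k normalization
leaks sequencing depth through the zero pattern: on synthetic data PC1
correlated 0.97 with log UMI total and split large cell types by depth.
Depth regression is standard practice in the toolchain this pipeline
mirrors. Component signs are fixed (largest-magnitude loading positive).

## Batch correction

The correction is the described soft k-means centroid scheme, not a
clone of the published Harmony algorithm: no ridge-regression correction
model. Per iteration: (i) soft assignment of cells to k clusters by a
Gaussian affinity on L2-normalized coordinates, multiplied by a
diversity penalty ((E+1)/(O+1)) raised to `diversity_strength`, where O
and E are the observed and expected cluster-batch masses from the
previous iteration; (ii) global and per-batch centroids per cluster in
the *original* coordinate space; (iii) each cell moves by the
responsibility-weighted difference (global − own-batch centroid).
Iteration stops when the maximum centroid movement drops below `tol`
(default 1e-4) or after `max_iter` (20).

Defaults: k = min(100, n/30), σ = 0.3, diversity_strength = 2. The
bandwidth matters: at σ = 0.1 the assignments are nearly hard, every
soft cluster becomes batch-pure, and the correction degenerates to a
no-op (measured post-correction batch entropy 0.13–0.4 versus ~1.0 at
σ = 0.3 on the default synthetic data). The diversity exponent 2 matches
the convention of the method family. A single batch returns the input
unchanged.

## Clustering

Shared-nearest-neighbor graph in the Seurat convention: an edge joins
every pair of cells whose kNN lists (k = 20, self included) overlap,
weighted by Jaccard overlap and pruned below 1/15; Leiden
(RBConfiguration, resolution 1.0, seeded, 2 iterations) partitions it.
Cells are lexicographically sorted internally so the partition is
independent of input order; singleton communities merge into the nearest
cluster by centroid distance; labels are renumbered by decreasing size.
A caveat verified against the R reference implementation: modularity
clustering at resolution ~1 inherently over-splits large *uniform*
point clouds (two 150-cell Gaussian blobs yield 3–4 clusters in both
implementations); this is a property of the objective, not a defect of
either implementation.

## Marker detection

One-vs-rest Wilcoxon rank-sum per cluster and gene, midranks for ties.
Exact mode enumerates all labelings of the pooled midranks (used
automatically for pooled sizes ≤ 12; valid under ties); otherwise the
normal approximation with tie-corrected variance and 0.5 continuity
correction. Note the approximation genuinely differs from the exact p by
up to ~0.04 (continuous) and more under heavy ties at such tiny sizes;
at the sample sizes where it is actually used it sits within 0.02 of a
100 000-draw permutation p. The fold change is computed on the de-logged
scale, log2((mean expm1 + 1)/(mean expm1 + 1)), consistent with the
0.36 ⇔ 1.28 correspondence. Selection criteria: log2FC ≥ 0.36, raw
P ≤ 0.01, expressed in ≥ 25% of the target cluster. No multiple-testing
adjustment is applied to the criterion (a Bonferroni column is emitted);
the two-sided p is paired with the one-directional fold requirement.
Clusters of fewer than 3 cells are tested but flagged low-power.

Calibration: with labels independent of the tested genes the test
rejects at the nominal level (measured 0.009–0.011 at p ≤ 0.01 on
no-signal data). Testing the very genes that built the clusters measures
selection bias instead — on the same null data that fraction is ~0.05 —
so the calibration check derives cluster labels from a held-out gene
subset (the count-splitting idea).

## Annotation

Marker transfer drops homology records above the e-value cutoff (1e-5)
and, under the default best-hit policy, keeps each reference gene's
smallest-e-value target (ties by target ID). For cluster c and type t
with detected set D = markers(t) ∩ upregulated(c):

* m₁ = |D| / |markers(t) present in the dataset| — marker quantity;
* m₂ = min(1, mean log2FC over D / 3.0) — fold magnitude on a
  saturating ramp (3.0 ≈ 8-fold);
* m₃ = mean expressing fraction over D;
* S = 0.20·m₁ + 0.50·m₂ + 0.30·m₃.

Mapping the three raw metrics to [0, 1] before weighting is this
module's main interpretive decision — weights on incommensurate raw
scales would be meaningless. Per cluster the argmax type is assigned;
exact ties are labeled ambiguous, and a best score below 0.05 is
unassigned.

## Cell cycle

The phase score is a binned-control module score: genes ordered by mean
expression are cut into 25 equal-size bins; for each target gene 50
control genes are sampled without replacement from its bin (the whole
bin when smaller); the score is the mean over targets minus the mean
over the pooled unique controls. The highest-scoring phase is assigned
unless all scores fall below 0.3 (non-cycling); argmax ties break by the
fixed order G1 < S < G2 < M and are flagged. The 0-threshold variant
reported elsewhere for the same protocol is selectable. The score is a
contrast against expression-matched genes, so it detects cell-specific
activation, not global mean shifts — a set shifted uniformly in *every*
cell is partly absorbed by bin reassignment.

## Transitional clusters and trajectory

A cluster is transitional when its CL/CT cell-count ratio lies in
[0.5, 2.0] (a window containing the reported ratios 0.93, 1.65, 1.49
with symmetric log-scale margins — a declared default, not an
established fact) **and** at least 25% of its cells have positive module
scores for both the epidermal and the trichome marker sets. Clusters
entirely from one sample class are never flagged.

Pseudotime is a deliberately minimal, fully specified construction, not
a reversed-graph-embedding method. The trajectory subset (clusters
annotated epidermis/transitional/trichome/guard plus flagged
transitional clusters) is re-embedded by PCA on its *ordering genes* —
the genes passing the marker criteria in any trajectory cluster, the
convention of the trajectory toolchain this substitutes for — centered
but **unscaled** (unit-variance scaling over-inflates markers of small
populations and distorts the geometry), with depth regressed out and
batch corrected. The embedding is denoised by kNN averaging (30
neighbors, 4 rounds), summarized by seeded k-means landmarks (30), and
spanned by a Euclidean MST. The root is the landmark nearest the
centroid of the epidermis-annotated cluster (the transitional flag only
breaks ties between several epidermis-annotated clusters). A cell's
pseudotime is its landmark's tree geodesic from the root plus the signed
projection of its offset onto the landmark's incoming tree edge
(clipped at zero) — the signed form keeps the ordering monotone along a
one-dimensional manifold, which an unsigned distance cannot.

The branch point is found by tips divergence: tip 1 is the landmark
farthest from the root; tip 2 is the landmark farthest off the
root→tip 1 path whose side subtree carries at least max(3, n/50) cells
and at least 10% of the main path's geodesic extent; the branch node is
where that subtree attaches. (A pure mass-balance rule is degenerate in
practice: heavy-but-shallow noise forks inside dense cell clouds outrank
the true bifurcation, and junctions adjacent to the root are missed.)
State 1 is the root side, states 2 and 3 the two branches, state 3 the
branch with greater mean pseudotime. A path-like tree yields two states
with a warning.

Gene trends are per-gene means over 20 equal-count pseudotime bins,
z-scaled, k-means-clustered into 3 modules renumbered by trend-peak
position (early → late); constant genes are dropped with a warning.
Branch dependence is a two-branch rank-sum contrast per gene with fold
changes of each branch against the pre-branch state, ranked by p with
|z| breaking underflow ties — a simplified substitute for
spline-likelihood branch models.

## Synthetic data

The generator emulates the three-sample study design: per-sample cell
type proportions (CT enriched for trichome and transitional cells and
depleted of guard cells; CL samples dominated by mesophyll, vascular and
epidermal cells), 1000 cells per sample, 2000 genes, 20 markers per
type, marker fold effect θ = 4, per-sample per-gene log-normal batch
shifts (σ = 0.3), log-normal library sizes (σ = 0.35, mean total 2500),
negative-binomial counts (size 10; Poisson in the limit), 300 ambient
barcodes per sample at ~40 UMIs.

The differentiation axis is a latent time t ∈ [0, 1] with disjoint type
spans (epidermis 0–0.30, transitional 0.34–0.66, trichome 0.70–1.0;
guard cells occupy the branch for t > 0.4). All trajectory programs are
continuous in t so the trajectory is a genuine Y in expression space:
the epidermal module falls and the trichome module rises along per-gene
logistic sigmoids; the transitional module is a trapezoid (full strength
across the transitional span, 0.05-wide linear ramps); on the guard
branch the trichome and transitional modules are released over a
0.15-wide window after the branch point while the guard module ramps on,
and the epidermal module freezes at its branch-point level (guard cells
retain epidermal identity). Earlier discontinuous variants (discrete
marker blocks switching at type boundaries) made the landmark MST
topology unstable — the guard arm could bridge the epidermis and
trichome ends — and were rejected.

Cell-cycle structure: 15 genes per phase multiplied by 2.5 in cells of
the matching phase; phase proportions per type put the trichome G2 share
at 0.375 (the endoreduplication signature) versus 0.25 elsewhere, with
10% non-cycling truth everywhere. The phase fold 2.5 keeps the cycle a
secondary axis of variation relative to cell identity, as in real data,
while leaving module-score margins comfortably above the 0.3 threshold.

The homology table maps each reference marker to its target gene with
e-values drawn in [1e-30, 1e-10], plus weaker secondary hits (1e-9 to
1e-6, exercising best-hit resolution) and decoy pairs above the cutoff
(1e-4 to 1e-1) that must never transfer.

Barcode-rank profiles for cell-calling tests draw real totals from
LogNormal(ln 2000, 0.4) and ambient totals from LogNormal(ln 30, 0.8) —
parameters chosen so the 1st percentile of the real distribution sits
far above the knee threshold, the well-separated regime the recall
checks assume; overlapping settings warn rather than fail.

What the generator does **not** emulate: doublets, ambient RNA
contamination inside real cells, gene–gene correlation beyond the
programmed modules, isoform/UMI artifacts, or batch effects with
structure beyond independent per-gene shifts. Passing recovery tests on
this generator therefore shows the pipeline implements its stated
procedures correctly and recovers planted structure of realistic
magnitude; it does not certify performance on real tissue.

## Reproducibility and problem sizes

All randomness derives from one integer seed through named per-stage
substreams (CRC32 of the stage name mixed into a SeedSequence), so
stage re-ordering never perturbs another stage's draws; repeated runs
are byte-identical. The default test and acceptance problem size —
3 samples × 1000 cells, 2000 genes — is large enough that every
recovery criterion has comfortable statistical margin while a full
pipeline run takes a few seconds on one CPU; unit tests use smaller
instances of the same generator.
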