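# Methods

## The statistical problem

A perturbation study compares single-cell transcriptomes between two
conditions (control vs mutant, or two brain regions). Classical
differential expression conditions on cluster assignments, so its power and
error rates are entangled with cluster sizes and boundary placement. The
pipeline implemented here scores genes and cells directly on the
neighbourhood structure of the data and only aggregates to populations at
the end, when cluster-level summaries are wanted.

## Cluster-free differential analysis

### Gene scores

Let `x_g` be a gene's normalized expression over all cells (counts scaled
to 10,000 per cell, log1p).

*Within-condition pattern score.* Two diffusion operators are applied: the
kNN average `A_knn` (unweighted mean over each cell's k nearest neighbours,
self excluded) and the random average `A_rand` (mean over k uniformly drawn
cells, self excluded). The score is

    s_g = cos(x_g, A_knn x_g) − cos(x_g, A_rand x_g).

A constant gene scores 0 (both cosines are 1); a gene confined to a tight
neighbourhood keeps high cosine under kNN diffusion but collapses under
random diffusion. Cosines with an all-zero vector are defined as 0, making
the score total. The default k is 30; diffusion is unweighted and excludes
self, the plainest reading of neighbourhood smoothing.

*Cross-condition score.* For each cell, the gene is diffused over its k
nearest same-condition neighbours and its k nearest other-condition
neighbours in the shared embedding, giving vectors `u_g` and `v_g`; the raw
deviation is `d_g = 1 − cos(u_g, v_g) ∈ [0, 1]`. The raw deviation scales
with a gene's expression level (low-expression genes are noisy under any
split), so the pipeline ranks genes by the deviation in excess of the same
quantity computed under a randomly permuted condition labelling — the same
logic as the random-diffusion baseline of the within score. The exposed
`cross_condition_score` returns the raw deviation; `run_emergene` performs
the baseline subtraction.

### The combinatorial signature

The signature is the union of the top `n_top_within = 10` genes by pattern
score and the top `n_top_cross = 90` genes by (baseline-corrected)
cross-condition score, with per-gene provenance and ordering by best rank.
The asymmetric default is deliberate: within-pattern genes are
condition-shared identity genes, and because the per-cell score is an
unweighted mean, every identity gene dilutes the differential contrast the
permutation test is meant to detect. A hundred genes total matches the
scale of the feature sets used elsewhere in the package (top-200 sets at
full study scale; half that at desk scale). Both knobs are exposed in
`RunConfig`.

### Per-cell permutation test

Genes are binned by mean normalized expression into deciles and, within
each mean decile, by variance into deciles (10 × 10 joint bins, rank-based
so bins are equal-sized). Each of `n_control_sets` (default 10,000; the
benchmark harnesses use 1,000) control sets replaces every signature gene
by a uniform draw from its joint bin. Control genes are *not* excluded
from their own bins: an exclusion variant was evaluated and rejected
because selection bias (top-by-noise genes are atypical of their bins) made
the null anti-conservative and coupled cell scores to which populations'
markers happened to enter the signature.

Per cell, the raw score is the mean normalized expression over the gene
set; the normalized score is `z_i = (raw_i − mean_ctrl,i) / sd_ctrl,i`
(standard deviation across that cell's control sets, floored at 1e-8), and
the one-sided empirical p-value pools the normalized control scores over
all cells and sets:

    p_i = (1 + #{control z ≥ z_i}) / (1 + n_cells · n_control_sets).

The smallest attainable p is therefore 1/(1 + n_cells·n_control_sets).
Normalization per cell against the cell's own control distribution (rather
than a global standardization) was chosen so that library-size and
complexity differences between cells cancel inside the z-score.

### Population summaries

Per group: the fraction of cells with p < 0.05, the gliding p (50th
percentile of the group's p-values, linear interpolation), a flag at ≥50%
significant cells, and an `analyzed` marker that is false under 10 cells.
`run_emergene` groups by (cluster, condition): with a one-sided enrichment
score, a condition-specific program elevates only the affected condition's
cells, so pooling both conditions into one group would cap the significant
fraction near 50% by construction.

## Marker scores and gene-set scores

For gene g and cluster c, `λ_gc` is the cosine similarity between the
gene's normalized expression vector and the cluster's 0/1 indicator;
the marker score is `λ²_gc / (λ²_gc + μ Σ_{c′≠c} λ²_gc′)`, 0 for silent
genes. μ defaults to 1; reference-gene selection for deconvolution-style
uses runs with μ = 100, a 10% within-cluster detection floor, and the
deduplicated union of per-cluster top-100 sets. Ties in rankings break by
gene id, making marker sets fully deterministic, and top-n sets are
prefixes of top-m sets for n < m.

Gene-set expression scores subtract a binned control pool: genes are cut
into 25 equal-size bins by mean normalized expression, and for every bin
touched by the set, `ctrl_size` (default = set size) control genes are
drawn from that bin. Under an exchangeable null the scores are centered at
zero up to residual bin-level offsets.

## Cross-modality label transfer

The shared embedding has one dimension per annotated reference type and one
per unsupervised Leiden cluster of the query panel; each dimension is the
gene-set score of that population's top-15 markers, computed in every cell
of both modalities on the shared gene panel after per-modality
re-normalization (re-normalization was chosen because panel restriction
changes each cell's total counts). Keeping the query-cluster dimensions in
the classifier's feature space preserves query-side structure the reference
types do not span.

Modality integration defaults to moment matching — each dimension is
standardized within modality and rescaled to the pooled mean/sd, so
per-dimension modality means agree to numerical precision — with a hook for
an external integration callable under the same contract. Labels transfer
by RBF-kernel SVM (`C = 1`, bandwidth `1/(D·var)`, balanced class weights);
reference classes under 5 cells are dropped with a warning.

## Triangular affinity map

All six similarity inputs (three target–anchor, three anchor–anchor) are
jointly min–max normalized. The three internal angles at the target vertex
are proportional to anchor-pair dissimilarities `1 − ŝ` and sum exactly to
360°; edge lengths are `ε + (1 − ŝ_target,anchor)` with ε = 0.05 so a
maximal similarity (forced to 1 by min–max) cannot collapse an edge. Both
direction choices — similar anchors at smaller mutual angle, similar pairs
at shorter edges — are conventions fixed here and pinned by tests. With all
six inputs equal the normalization is undefined and values default to the
midpoint 0.5, giving the symmetric 120° layout. The target sits at the
origin, the first anchor on the positive y-axis, the others counterclockwise.

## Laminar assignment and composition statistics

Interneurons take the plurality layer of their five nearest excitatory
neighbours (KD-tree, leaf size 6); ties break by the layer of the nearest
neighbour belonging to a tied class — a deterministic, locality-respecting
rule. Composition tables report per-group type fractions, with an optional
external denominator (reference population size or tissue length) replacing
the group total. Group comparisons use the two-sided Wilcoxon rank-sum
test: exact null distribution for combined n ≤ 25 without ties, normal
approximation with tie correction otherwise, and no multiple-comparison
correction, matching the study conventions the package targets. All-tied
inputs return p = 1.

## Synthetic data

Counts are negative binomial with mean μ and dispersion θ (variance
μ + μ²/θ; θ = 2 by default), sampled as a Gamma–Poisson mixture.
Per-gene baseline means are lognormal around `nb_mean` = 0.5
(`gene_mean_sigma` = 0.5), because real transcriptomes span orders of
magnitude in expression; a flat baseline makes every planted gene a
statistical clone of its peers, and mean/variance-matched controls then
absorb planted signals entirely — a degenerate corner with no biological
counterpart. Per-cell library sizes are unit-mean lognormal (σ = 0.3).
Planted markers multiply their type's means by a fold (8 by default);
condition effects ablate a type, rescale its abundance (with
renormalization), or multiply a gene program's means in the target type.
The exchangeable-null generator keeps `gene_mean_sigma` = 0 and applies no
effects, so the two conditions are a random split of one homogeneous
population. The spatial scaffold places excitatory cells uniformly in
non-overlapping laminar bands and interneurons in their band with Gaussian
vertical jitter.

What the generators do not emulate: ambient RNA, doublets, batch structure
within a modality, gene–gene correlation beyond cell-type structure, and
imaging-specific spatial noise (optical crowding, segmentation errors).
Passing tests therefore demonstrate the statistics behave as designed under
their stated noise model, not that real tissue meets that model.

## Problem sizes and numerical choices

The benchmark harnesses (`sskit.benchmarks`, driven by the test suite and
`scripts/acceptance.py`) run at desk scale, chosen so a full pass completes
in minutes on one CPU: 2,000 cells × 1,500 genes, 1,000 control sets and
10 seeds for the calibration and power experiments; 2,000 + 2,000 cells
with a 300-gene panel (capture 0.5, modality scale 1.5) for label
transfer; brute-force oracle comparisons at 150–1,000 elements with
tolerance 1e-10. Pearson residuals use θ = 100 and are clipped at
√n_cells before variance ranking; SVD components fix their sign by making
each component's largest-magnitude loading positive; kNN ties break by row
index ascending; Leiden uses the RBConfiguration objective at resolution 1
with an explicit seed. Empirical p-values are never 0 by construction.

## Known limitations

- Exactly two conditions; no covariate adjustment or spatially-aware nulls.
- The cross-condition gene score is one consistent construction of a
  neighbourhood-contrast statistic; other readings (for example symmetric
  divergences of the two diffusion maps) would differ in detail.
- The per-cell score is an unweighted mean over the signature; a weighting
  hook exists but no weighting scheme is shipped.
- Laminar recovery degrades at touching band boundaries, where k-NN votes
  legitimately cross layers; this is a property of the estimator, not a bug.
- The moment-matching integrator removes location/scale modality effects
  only; nonlinear distortions require the external hook.
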