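# Methods

## Model and rationale

Bulk tumour expression profiles are mixtures. Writing `p_kj` for the
proportion of cell type `k` in sample `j`, the measured intensity of a gene
expressed specifically in that cell type is, to first order, proportional to
`p_kj`. Because `p_kj` varies across biopsies, all genes of one cell type
covary, and the sample-wise Pearson correlation between two such genes is
high regardless of which tumour entity is profiled. The pipeline estimates
these latent programs by thresholding the all-pairs correlation matrix into
a graph, partitioning the graph with Markov clustering, and — for the
cross-cohort analysis — averaging correlation matrices entrywise over
cohorts before thresholding, so that only relationships reproduced in every
cohort remain strong enough to form edges.

Correlations are computed on natural-scale normalised intensities, not on
logarithms: the graph construction this package implements operates on
natural-scale values throughout, and all of its thresholds (0.6–0.8) are
calibrated on that scale. Only positive correlations form edges; negative
correlation in this setting mostly reflects compositional closure (more of
one cell type means less of another) and carries no module information at
the thresholds used.

## Threshold selection

The per-dataset threshold is chosen from a grid (default 0.60–0.95, step
0.01) so that the fraction of probesets retained as connected nodes is as
close as possible to a target (default 40%). Ties are broken toward the
lower threshold, which retains more data. "Fraction of data" is interpreted
as the node-inclusion fraction — probes with at least one edge over all
probes — rather than an edge count; node inclusion is the quantity that the
40%-of-the-transcriptome design target directly constrains.

## Markov clustering

The implementation is the canonical weighted MCL on a dense matrix:

1. symmetric adjacency from edge weights, self-loops of weight 1 added;
2. column normalisation to a stochastic flow matrix;
3. iterate expansion (matrix squaring) and inflation (entrywise power,
   default 2.2, then column renormalisation), zeroing entries below 1e-5
   and renormalising, until the maximum entrywise change falls below 1e-6
   or 100 iterations elapse (non-convergence returns the current state with
   a warning flag rather than raising);
4. attractors are rows with positive diagonal in the limit; attractors
   linked by residual flow form one attractor system; every other node
   joins the system it flows into;
5. a node attracted by several systems joins the larger cluster, ties going
   to the cluster containing the lexicographically smallest node — MCL can
   emit overlapping attractor systems and a deterministic resolution is
   required for reproducibility;
6. clusters are sorted by size (largest = "Cluster 1"); isolated nodes
   become singletons (or are reported unassigned on request).

Convergence is tested by entrywise change rather than idempotence
(`M² ≈ M`), which is equivalent at tolerance and costs an extra matrix
multiplication per iteration. Pruning at 1e-5 keeps the dense iteration
cheap without altering small-graph results. The test suite cross-checks
partitions against a second, independently written MCL (no pruning,
idempotence convergence, component-based readout) on planted-partition
benchmarks; the two routes agree exactly on essentially all such graphs
once both are run to full convergence — an under-converged limit matrix is
the main way the two readouts can diverge, which is why the reference
iterates to a 1e-12 idempotence tolerance.

## Conservation mapping

Whether a merged-network "core signature" recurs in an independent dataset
is decided by a one-sided hypergeometric (Fisher) test on the overlap
between the signature and each cluster of the independent dataset. The
universe is the set of probe identifiers observable in *both* analyses —
enrichment is only meaningful over mutually observable features — and
p-values are adjusted jointly across all (signature, cluster) pairs,
Benjamini–Hochberg by default with Bonferroni available. Conservation
mapping runs at probeset level (clusters are probeset sets); generic GMT
enrichment collapses probesets to gene symbols first, so several probesets
of one gene count once. Odds ratios use the Haldane 0.5 correction when a
2×2 cell is zero.

The one-sided hypergeometric test is discrete, so its null calibration
depends on the expected overlap: with an expected overlap near zero the
test is strongly conservative, while for cluster sizes around 150–250 in a
universe of a few thousand (expected overlap ≈ 10) the attainable p-values
are dense enough that the fraction of null pairs below 0.05 sits in the
0.03–0.05 range. The calibration check in the test suite uses cluster sizes
in that regime, chosen by this closed-form tail analysis; with very small
clusters the same check would "pass" only by being conservative.

## Simulator

`simulate_tumor_dataset` draws, per sample, cell-type proportions from
`Dirichlet(α)` (default α = 1 per program: broadly varying compositions)
and per activity program an independent `Beta(2, 2)` level — the cell-cycle
analogue, deliberately decoupled from composition. Gene `g` of cell-type
program `k` takes the value `b_g · (c0 + p_kj) · exp(ε)`,
`ε ~ N(0, σ²)`, with amplitude `b_g ~ LogNormal(ln 100, 0.5)` and baseline
`c0 = 0.05` (arrays have background signal; a cell type absent from a
sample still yields positive intensity). Housekeeping genes use a constant
driving level of 1, so only noise varies. Each gene emits 1–3 probesets
(default probabilities 0.6/0.3/0.1) with a per-probe gain
`LogNormal(0, 0.2)` and extra probe noise of standard deviation σ/2. Noise
is multiplicative log-normal and output is natural-scale, matching how
microarray intensity noise behaves. Default σ = 0.15 yields within-program
correlations around 0.9 — the regime in which real cell-type modules are
detected at thresholds of 0.6–0.8.

Dataset-specific programs (tumour-type-private biology) are driven by a
separate Dirichlet over the specific programs plus one silent remainder
component: their levels vary in [0, 1] and are mutually anti-correlated
like true cell fractions, while the cell-type proportions proper keep
their exact sum-to-one closure, which the ground-truth container asserts.
In multi-cohort simulation the shared genes keep an identical probe
universe across cohorts (probeset multiplicities drawn once from the master
seed); specific genes are minted per cohort with disjoint names, so the
probeset intersection step removes them from the meta-analysis — exactly
the behaviour expected of platform-private or cohort-private features.

What the simulator does *not* model: probe sequence effects, batch effects,
copy-number signal, dropout, or correlated noise between programs. Passing
the recovery benchmarks therefore demonstrates that the pipeline correctly
inverts the mixture-of-programs generative model, not that it is robust to
every artefact of real microarray cohorts; on real data the QC and
normalisation upstream of this package carry that burden.

## Layout

The 3-D layout is a plain Fruchterman–Reingold scheme with the attractive
force along each edge scaled linearly by its correlation weight, seeded
uniform initial positions in the unit cube, all-pairs repulsion, and a
displacement cap cooling linearly to zero over the iteration budget
(default 100). It is deterministic given the seed and is intended for
export and inspection, not for reproducing any particular rendering.

## Problem sizes and numerical choices

The bundled benchmarks run at desk scale by design: single-dataset recovery
uses 3–4 cell-type programs × 50 genes, 20 housekeeping genes and 150
samples (≈ 250–380 probesets); the conservation benchmark uses six training
cohorts plus one held-out cohort of the same design; MCL reference
agreement uses twenty 48-node planted-partition graphs; the null
calibration accumulates ≥ 2000 cluster pairs over a 4000-identifier
universe. The full test suite and the acceptance script each complete in
seconds. Correlation matrices may be computed in row blocks for memory;
results are block-size independent to 1e-12 (BLAS summation order differs
between shapes at the last bit). Zero-variance probes yield undefined
correlations, which never form edges and propagate through the
mean-correlation merge as undefined.

## Known limitations

* Real cohort-scale graphs (tens of thousands of probesets) require a
  sparse MCL variant for comfortable memory use; the dense implementation
  here is exact and adequate up to a few thousand nodes.
* Cluster counts on real data depend on the exact MCL parameterisation
  (self-loops, pruning) of the tool that produced them; this implementation
  fixes canonical choices (loops = 1, prune at 1e-5) and documents them
  rather than matching any particular tool's output cluster-for-cluster.
* The 40% node-inclusion reading of threshold selection is a recorded
  design interpretation; edge-count-based selection would pick slightly
  different thresholds on the same data.
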