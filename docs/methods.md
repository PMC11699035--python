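# Methods

This note documents the models, statistics and numerical conventions
implemented in `immunopheno`, the defaults they ship with, and what the
synthetic-data experiments do and do not demonstrate.

## Cytometry transforms

Raw fluorescence or mass-cytometry intensities are mapped to a display
scale before any clustering.

**Arcsinh.** `x -> asinh(x / cofactor)`; the cofactor defaults to 5 for
mass cytometry and 150 for fluorescence (community conventions — neither is
dictated by the data, both are config knobs). The transform is strictly
monotone, defined for negative values, and exactly invertible.

**Logicle.** The biexponential display transform parameterized by the top
of scale `T`, linearization width `W` (decades), total decades `M` and
extra negative decades `A`. We implement the standard published
parameterization: the display-to-data map is
`B(y) = a e^{by} - c e^{-dy} - f` with coefficients fixed by `(T, W, M, A)`
and `d` the root of `2(ln d - ln b) + w(b + d) = 0`. The forward transform
solves `B(y) = x` by safeguarded bisection (deterministic, ~1e-14
relative); the inverse is the closed form. Round-trip accuracy is checked
on a 100,000-point grid including negatives (max relative error ~4e-9).

*Automatic parameterization.* Per channel: `T` = observed maximum,
`M` = 4.5 decades, `W = (M - log10(T/|r|))/2` with `r` the 5th percentile
of the channel's negative events (`W = 0` when there are none), clamped to
`[0, M/2]`, `A = 0`. Degenerate channels (constant, or no positive values)
fall back to arcsinh and the fallback is recorded in the parameter record.

*Joint stained/unstained convention.* Parameters are estimated on the
merged stained + unstained events and then applied to each table, so
matched control samples undergo the identical transform. By construction,
transforming the merged table and splitting equals transforming each table
with the merged-fit parameters, bit for bit.

*A note on the `W = 0` limit.* With `W = 0, A = 0` the biexponential
reduces to a sinh-like map `a(e^{by} - e^{-by})`. It agrees with the pure
log mapping `y = 1 + log10(x/T)/M` only where the negative exponential is
negligible — numerically, to 1e-6 relative for `x >= T * 10^{-1.5}` at
`M = 4.5` — and the discrepancy grows toward the bottom of scale. Our
tests assert the 1e-6 agreement on that domain and the monotone decay of
the discrepancy with increasing `x`.

## Rule-based gating

Manual gating is replaced by explicit threshold gates with audit reports
(`events_in`, `events_out`, rule, threshold). All quoted thresholds are
strict inequalities: the leukocyte gate keeps events with CD45 **> 0.5**
on the arcsinh scale (mass-cytometry mode), samples are capped at
**500,000** events by a seeded uniform subsample, viability gates keep
events with stain strictly below threshold, and the doublet rule is a
ratio gate on area-vs-height proxy channels (a no-op with a warning when
no such pair exists). Gates never reorder surviving events.

## Phenoclustering

`PhenoGraphClusterer` implements kNN–Jaccard–Louvain clustering:

1. **Exact kNN** (Euclidean), `k = 60` by default. Distance ties break by
   node index; inputs up to a few thousand events use full pairwise
   distances so the tie-break is exact.
2. **Jaccard re-weighting.** The directed kNN lists are symmetrized into
   an undirected edge set; each edge `(u, v)` is weighted by
   `|N(u) ∩ N(v)| / |N(u) ∪ N(v)|` over the two k-neighbor sets.
   Zero-Jaccard edges are pruned.
3. **Louvain modularity maximization**, written from scratch: repeated
   local node moves (seeded sweep order; equal-gain moves resolve to the
   lowest community id) followed by community aggregation, iterated to
   convergence, with the resolution parameter multiplying the
   configuration-model null term. Several seeded restarts are run and the
   highest-modularity partition is kept. On small graphs (<= 512 nodes)
   restarts beyond the first start from seeded random community
   assignments: greedy moves from all-singletons can share a single
   shallow basin on tiny dense graphs, and random initializations
   demonstrably reach the exhaustive-search optimum on every graph of
   oracle-checkable size (<= 8 nodes, all partitions enumerated). Large
   kNN graphs use the classic scheme; on the default synthetic cohort our
   partitions match or exceed the modularity reached by igraph's
   multilevel implementation.

**Two-round scheme.** Round 1 clusters all merged events; clusters with
low median CD45 are removed with their events (debris, non-immune
material); survivors are re-clustered. "Low CD45" has two modes:

- `absolute` — median strictly below a given value (the mass-cytometry
  convention, 0.5 on the arcsinh scale);
- `quantile` (default) — median strictly below the q-th per-cluster-median
  quantile (q = 0.25), where the quantile is the **lower order statistic**
  (`sorted_medians[floor(q * (n_clusters - 1))]`). Because the cut
  coincides with an actual cluster median and the comparison is strict, a
  cluster tying the cut always survives; a linearly interpolated
  percentile can land between two clusters of the same CD45-mid
  population and silently delete half of it (we observed exactly this
  with split microglia before adopting the order-statistic convention).

**Bootstrap stability.** Cluster robustness is the clusterboot-style mean
bootstrap Jaccard: resample events with replacement, re-cluster with the
same parameters, score each original cluster by its best Jaccard overlap
with any new cluster (computed over bootstrap draws), and average over
replicates. Clusters absent from a resample skip that replicate and the
number of contributing replicates is reported. A cluster is called stable
when its score strictly exceeds **0.75**. `n_boot` defaults to 50 in the
API; the acceptance experiments use 20 replicates, which stabilizes the
score to well within the margins being tested at the default cohort size.

**Embeddings** (t-SNE via scikit-learn, UMAP via the optional plug-in) are
presentation output only; no analysis step consumes the coordinates.

## Composition statistics

Per-cluster marker summaries report channel medians discretized to
lo/mid/hi by tertiles of the per-cluster medians within each channel
(strictly below the lower tertile = lo, strictly above the upper = hi).
Because tertile levels are purely relative, a channel carrying no real
signal in any cluster would still hand out "hi" labels; channels whose
cluster-median spread falls below 20% of the widest channel's spread
(`min_spread_frac`, exposed) are therefore treated as non-informative and
report "mid" for every cluster. Annotations come from an ordered,
user-editable marker-rule table (first match wins); the shipped defaults
encode the phenotype logic of CD45-enriched brain-tumor infiltrates —
microglia vs MDM discriminated by CD45 lo vs mid/hi at shared CD14
positivity, neutrophils by CD66b, and the noncanonical CD3+ myeloid and
CD19+ myeloid subsets by lymphoid markers on a myeloid background.

Sample x cluster composition fractions use either the kept (CD45+) events
as denominator (rows sum to 1) or per-sample pre-filter totals; zero
denominators produce flagged NaN rows, never silent zeros. Pearson and
Spearman correlations of fractions carry two-sided p-values from
`t = r sqrt(n-2) / sqrt(1-r^2)` on `n-2` degrees of freedom (Spearman uses
the same t approximation on ranks); p-values below 2.2e-16 are displayed
as a floor string alongside the raw float. Both methods are first-class
and recorded in output metadata.

## Bulk normalization and deconvolution

Bulk counts are normalized TPM → quantile → log2 (flags recorded in
order). Quantile normalization replaces each sample's sorted values by the
cross-sample means of sorted values, mapping back by rank; tied values
receive the mean of the reference values over their tied rank range. With
that convention idempotency is exact on tie-free data; ties perturb the
reference distribution on a second pass, which is inherent to the
convention and covered by its own test.

Cell-type references are per-gene medians over purified samples
(mean-of-middle for even counts). Deconvolution regresses each bulk
sample's vector, restricted to immune-related gene-cluster genes, on the
reference columns with elastic-net regularization at mixing parameter
`alpha = 0.25`; the penalty `lambda` is chosen per sample by seeded
10-fold cross-validation over genes, stratified by expression decile, on a
60-point log-spaced path from the data-derived `lambda_max`. An intercept
is included by default (flag-exposed, since its presence changes the
coefficient scale). Raw coefficients are reported; a clipped-to-zero and
renormalized proportions view is provided as an explicitly derived
projection.

**Design scale.** Mixtures of cell populations combine *linearly* in
expression space, so the default regression design un-logs log2-flagged
inputs (`2^x - 1`) for both bulk and reference before fitting; weights of
linear mixtures are then recovered directly (the noiseless case matches an
ordinary-least-squares oracle to < 1e-3). Regressing the log2 values
as-is (`design_scale="log2"`) is available but estimates coefficients of a
model that is only approximately linear in the mixing weights.

## Immune gene-cluster (IC) activities

Per IC and cohort: (1) drop genes with sample variance strictly below
0.05 on the log2 scale (the only scale on which that default is
meaningful); (2) scale each gene's sample vector to [0, 1] after clipping
at its 2nd/98th percentiles (linear-interpolation percentile definition,
stated so tests are exact; degenerate genes are excluded and flagged);
(3) select the **largest group of genes that are pairwise positively
correlated** — formalized as a maximum clique in the positive-correlation
graph, the only reading that satisfies "pairwise ... with each other".
Exact clique search (maximal-clique enumeration, lexicographic tie-break)
is used up to 40 genes; above that a greedy peel iteratively drops the
gene with the most non-positive correlations, and the method used is
recorded in the output. When no positive pair exists the single gene with
the highest mean correlation is used. (4) The activity of a sample is the
median of the selected genes' scaled values — in [0, 1] by construction
and invariant under monotone affine rescaling of the raw values.

## Single-cell analysis

QC filters, in order: cells expressing < 200 genes removed; genes
expressed in < 3 cells removed; cells with mitochondrial fraction not
strictly under 5% removed ("expressed" means value > 0; mitochondrial
genes by `MT-` prefix or an explicit list). Stage-wise counts are
reported and an empty result is an error.

Overexpression calls: per gene, a cell type is called when its average
expression strictly exceeds the across-type mean + 0.5 SD (sample SD,
n−1 denominator; flag-exposed since the convention is not dictated).
When the SD is zero no type is called. Each IC's genes are subclustered
by agglomerative hierarchical clustering of the binary call vectors
(Euclidean distance on 0/1, complete linkage), cut at a requested count
or auto-selected by mean silhouette over 2..min(8, genes−1); identical
call vectors collapse to a single subcluster with a note. The dotplot
table reports, per subcluster and cell type, the fraction of the
subcluster's genes called overexpressed in that type.

The differential-expression threshold filter keeps genes with logFC
strictly over 0.25 and Bonferroni-adjusted p (`p * n_tests`, capped at 1)
strictly under 0.05. The underlying test is a pluggable two-sided
Wilcoxon rank-sum stand-in with logFC as the difference of group means on
the working scale; model-based single-cell DE tests are out of scope.

## Synthetic data: what it emulates, and what it does not

The generators provide planted ground truth for every stage.

**Event cohorts.** Populations are Gaussian on the *transformed* (arcsinh,
cofactor 150) scale — the scale on which cytometry populations are
conventionally modeled — and mapped back through `sinh(z) * cofactor` so
the pipeline's own transform step is exercised. The default panel holds
the lineage markers CD45, CD3, CD4, CD8, CD14, CD19, CD66b plus FSC-A and
SSC-A size/granularity proxies and the viability stain as a separate
dimension. The default archetypes mirror the phenotype granularity of
brain-tumor immune infiltrates: two microglia subpopulations (homeostatic
and activated), monocyte-derived macrophages, neutrophils, CD4+ and CD8+
T cells, a CD45-low viability-high debris population (15%), and a 2%
noncanonical CD3+CD14+CD66b+ myeloid spike. Per-sample compositions vary
across the five default samples the way tumor types differ (one
microglia-dominated sample, infiltration-dominated samples, one
lymphocyte-rich sample); this variation is what makes the sample-
correlation analyses non-degenerate. Doublets, when enabled, are
channel-wise sums of two parent events (the standard idealization of
coincidence events) with parent indices retained for auditing.

Not emulated: spectral spillover/compensation, acquisition drift, batch
effects beyond per-sample fractions, and non-Gaussian population shapes.
Recovery results on this cohort therefore demonstrate the pipeline's
correctness on well-posed inputs, not robustness to instrument artifacts.

**Bulk mixtures** are exact linear mixtures of nonnegative reference
profiles with Gaussian noise added on the log2 scale (the analysis
scale); noise_sd defaults to 0.1. The synthetic reference panel boosts 30
marker genes per cell type 16-fold over a shared lognormal baseline, and
the matching gene clusters (one per type) double as the immune-gene
restriction set. Real purified references are noisier and collinear
(e.g. microglia vs macrophages); recovery r >= 0.95 here bounds the
regression machinery, not reference quality.

**Single-cell matrices** draw per-gene per-cell values from a Gaussian
working scale (log-normalized-like; `baseline_mean = 1.0`,
`baseline_sd = 0.5`) with program genes mean-shifted (+2 by default) in
their target cell types, and five `MT-` genes realizing a planted
per-cell mitochondrial fraction (default range 0.5–4%). Count noise,
dropout and library-size variation are not modeled.

## Problem sizes

The recovery experiments run at: 5 samples x 5,000 events (cytometry), 50
bulk mixtures of 6 reference types over 300 genes, 3,000 cells x ~680
genes (single cell), 20 bootstrap replicates for stability, 10 seeds for
planted-partition recovery, and 52 small graphs for the exhaustive
modularity oracle. These sizes were chosen so each estimate's sampling
error is far from the property bounds being tested while the full
experiment remains desk-scale.

## Known limitations

- Modularity maximization has a resolution limit: a single homogeneous
  population occupying a large share of the graph (roughly >25% at the
  default cohort scale) can be split by the *optimal* partition — we
  verified such splits carry genuinely higher modularity and are
  reproduced by independent implementations. The phenotype granularity of
  real cytometry data (many populations, each a modest share) sits in the
  stable regime.
- The CD45-low quantile rule assumes debris is a minority of clusters; a
  cohort that is mostly debris needs the absolute mode.
- Exact maximum-clique search is exponential in the worst case; above 40
  genes the greedy peel is used and its result, while always a valid
  positively-intercorrelated set, may be smaller than the maximum.
- The elastic-net intercept and the raw (possibly negative) coefficients
  follow the regression convention; the renormalized proportions view is
  a projection, not a statistical estimate of fractions.
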