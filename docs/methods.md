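# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the design decisions behind `degbrin`, in the order
the pipeline runs.

## Differential expression with variance moderation

Each gene's log2 expression within one brain region is modelled by ordinary
least squares on diagnostic group. Contrasts are simple two-group mean
differences fitted on pairwise sample subsets (MCI−CON, AD−CON, MCI−AD);
no covariates are included. For a two-group contrast with group sizes
(n₁, n₂) this gives the pooled-variance two-sample setting: coefficient
β̂_g = mean difference, residual variance s²_g on d_g = n₁ + n₂ − 2 degrees
of freedom, and unscaled coefficient variance v_g = 1/n₁ + 1/n₂.

Gene-wise variances are treated as exchangeable draws from a scaled
inverse-chi-square prior, σ²_g ~ d₀·s₀²/χ²(d₀). The moderated variance is
the posterior mean s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g) and the moderated
statistic t̃_g = β̂_g/(s̃_g·√v_g) follows a t distribution on d₀ + d_g
degrees of freedom. We use √v_g in the denominator: it is the only form
under which d₀ = 0 reduces exactly to the ordinary t-statistic.

(d₀, s₀²) are estimated by moment matching on log s²_g: under the prior,
log s²_g is a location-shifted log-F variate whose mean and variance are
closed forms in digamma/trigamma functions, so d₀ comes from inverting the
trigamma function (Newton iteration started at its asymptotic inverse) and
s₀² from the matched mean. d₀ is capped at 10⁶ to represent +∞; when the
observed dispersion of log variances does not exceed the sampling
dispersion, the prior degenerates to a point mass at the common (geometric
mean) variance. Non-finite moment estimates fall back to d₀ = 0 (no
moderation) with a logged warning. The implementation is validated in the
test suite against limma's `lmFit`/`eBayes` on a shared fixture, and
(d₀, s₀²) recovery on 2,000-gene simulated cohorts is within 20% of the
generating values.

DEG calling uses |log₂FC| > 0.585 (a 1.5-fold change) AND BH-adjusted
p < 0.05, both strict inequalities. Benjamini–Hochberg adjustment is the
step-up procedure with monotonicity enforcement, applied within each
(region, contrast) test family. Regions lacking two samples in either group
of a contrast skip that contrast with a warning rather than failing: sparse
region-contrast combinations are an expected feature of multi-region
cohorts.

Preprocessing (`dge.preprocess`) removes rows with missing values, collapses
duplicate gene ids by mean, and drops genes below a detection threshold in
more than 60% of samples. When no threshold is supplied, the 20th percentile
of the pooled value distribution is used. Synthetic cohorts emulate an
already-quality-controlled matrix (the generator plants no floor effects or
missingness), so pipeline runs on synthetic data apply differential
expression directly; the detection filter is exercised by its own unit tests
and is meant for raw real-data matrices.

## The DEG-BRIN graph

Per-region DEG sets are unions over the three contrasts. The universal list
G keeps genes differentially expressed in ≥ 2 regions (`min_regions`
configurable). Region sets are restricted to G before graph construction;
nodes are regions, an edge exists iff the restricted sets intersect, the
edge weight is the intersection size, and self-loops carry the restricted
set size. For graph convolution the adjacency is normalized symmetrically,
Â = D^(−1/2) W D^(−1/2) with D the diagonal of row sums, which keeps Â
symmetric with spectral radius ≤ 1; the positive self-loops guarantee
positive row sums.

PPI edge lists (gene_a, gene_b, combined score in [0,1]) are thresholded
inclusively (s ≥ τ) at tiers τ ∈ {0.4, 0.7, 0.9}. Hubs are nodes in the top
20% of both degree and betweenness centrality, computed on the thresholded
graph's nodes, with ≥-quantile boundary ties included (under heavy ties the
rule degenerates to returning all tied nodes, which is the only unambiguous
reading). Betweenness is the raw Freeman form — unordered endpoint pairs,
endpoints excluded, unweighted shortest paths, no normalization — computed
via networkx and cross-checked in the tests against an independent
path-enumeration oracle.

Random baseline graphs match node and edge counts exactly (uniform choice
among simple graphs with that edge count), keep the original self-loop
weights, and binarize off-diagonal weights to 1, so the ablation removes
the prior's structure and weighting while preserving its scale.

## The classifier

Input features for one sample are its standardized (z-scored per gene on
training-partition statistics) expression over G. Three feature modes decide
how the per-sample vector populates the node feature matrix H⁽⁰⁾:
`broadcast` copies the gated vector to every region node; `masked`
additionally zeroes genes absent from each node's restricted DEG set;
`per_node` accepts genuinely node-resolved features (used by the PPI-GCN
control, whose nodes are genes with scalar expression features). The gene
gate softplus(γ) multiplies input features and the region gate softplus(ρ)
multiplies pre-pooling node embeddings; both start neutral at 1 and their
fitted magnitudes are the importance scores. Dropout is applied after the
first convolution only; layer normalization is per node across the hidden
axis with a learnable affine; pooling is the mean over nodes; the head is a
3-class softmax.

The network is plain numpy. The backward pass is derived analytically for
every parameter block (including the layer-norm and gate paths) and the test
suite checks it against central finite differences at 10⁻⁴ relative
tolerance. Training uses Adam with decoupled weight decay; the defaults
(`hidden_dim = 103`, `dropout = 0.458`, lr = 7.03·10⁻³, weight
decay = 1.06·10⁻⁵) are the configuration selected by the validation-accuracy
search and are used throughout, including the model comparisons. Training
runs minibatches of 64 in shuffled order, random over-sampling of minority classes applied to
the training partition only, and early stopping with patience 20 on
validation loss, returning the best-validation-epoch parameters. A fixed
per-epoch subsample of the parameter-update vector is recorded for the
gradient-distribution report.

Splits are stratified 70/10/20 by class with largest-remainder rounding,
reconciled against the largest-remainder allocation of the totals so that
1,053 samples split exactly 737/105/211. Classes smaller than 3 go entirely
to training with a warning. Hyperparameter search is a seeded random search
(log-uniform in learning rate and weight decay) over hidden 64–256, lr
1e−4–1e−3, weight decay 1e−6–1e−3, dropout 0.3–0.7, 30 trials by default;
a tree-structured surrogate would add nothing at this budget and random
search keeps the trial log exactly reproducible.

## The synthetic cohort generator

`simdata.generate_cohort` emulates a multi-region postmortem design: one
sample per (subject, region), 19 regions by default, four diagnostic strata
deterministically consolidated to CON/MCI/AD. Baseline expression is
Normal(μ_g, σ²_g) on the log2 scale with μ_g ~ Normal(8, 1.5²) and
σ²_g ~ d₀·s₀²/χ²(d₀), defaults d₀ = 4, s₀² = 0.25 (residual sd ≈ 0.5),
chosen as calibration values typical of log-scale microarray residuals, and
matching the moderation model so the empirical-Bayes estimator has a
recoverable ground truth.

Planted differential expression: per region and contrast, `deg_per_region`
genes (default 30) receive an additive shift of magnitude
`effect_size_log2fc` (default 1.0) in the contrast's target group. A
`shared_fraction` (default 0.5) of each selection is drawn from a shared
pool; the remainder is region-private. Regions belong to contiguous
pathology-stage blocks (default 3 when there are enough regions; each block
needs several regions, so cohorts with fewer than 6 regions use one block),
and each block has its own pool — sharing therefore concentrates among
regions at a similar stage, giving the DEG-BRIN real block structure rather
than a uniform complete graph. The direction of each gene's dysregulation is
drawn once per gene and shared across regions, matching the multifocal
premise that a disease gene moves coherently where it is affected. Subjects
carry a severity factor (Gamma, mean 1, sd 0.4 by default) scaling their
shifts: diagnostic groups — the merged MCI stratum in particular — are
biologically heterogeneous, and this is the main driver keeping synthetic
classification accuracy near 0.8 rather than saturated.

What the generator does not emulate: probe-level artifacts, batch effects,
missingness, detection floors, gene–gene correlation beyond the planted
group structure, and any real disease biology. Passing tests therefore
demonstrate the pipeline's statistical correctness and its behavior under a
known truth — not performance claims about real cohorts.

## The graph-prior ablation

`compare_models` trains the DEG-BRIN GCN, a size-matched Random-GCN, and
optionally the PPI-GCN gene-graph control under identical splits and paired
seeds, in `masked` feature mode. Masked mode is used for comparisons because
in broadcast mode all node rows are identical and any graph enters the model
only through its row sums, which makes a topology ablation nearly
uninformative; with per-region masks the convolution actually mixes
region-specific views and the co-occurrence weighting can matter. On
planted-signal cohorts (effect 1.0, 30 subjects per group) the DEG-BRIN
prior yields a small but consistent paired-seed advantage in mean test
accuracy over the random baseline (the random graph's preserved self-loops
dominate its unit edges after normalization, making it a nearly
convolution-free model, while the BRIN's structured weights mix same-stage
region views coherently). The advantage is directional, of the order of one
to two accuracy points under these study conditions, and both models sit
well above chance; the gene-level PPI-GCN control, whose nodes carry only
scalar features, is markedly weaker at a matched training budget. The
acceptance script reports the PPI arm from a single seed with a bounded
epoch budget because the gene graph is an order of magnitude larger than the
region graph.

## Interpretation outputs

Importances are gate magnitudes (softplus of the raw gates), optionally
multiplied by mean absolute input gradients (`gate_x_gradient`); rankings
break ties lexicographically. Gradient statistics (mean, sd, min, max,
kurtosis) summarize the pooled per-epoch parameter-update samples; kurtosis
is the Pearson (non-excess) convention, value 3 for a normal distribution,
so "leptokurtic" means > 3. The triad table joins, for each top-ranked
region, the globally top-ranked genes found in that region's DEG set with
the significant (adjusted p < 0.05) enriched pathways containing at least
one of them. Enrichment itself is the exact hypergeometric upper tail
P(X ≥ k) computed in log space — a point probability is not enrichment
evidence — with BH adjustment across terms, and the background defaults to
the post-preprocessing gene universe.

## Problem sizes and degenerate inputs

The test suite and acceptance script run on cohorts of 200–2,000 genes,
2–19 regions and 8–30 subjects per group; oracle comparisons use ≤ 30-node
graphs (exhaustive path enumeration at 12 nodes) and 2,000-gene variance
draws. Degenerate inputs are handled explicitly: empty DEG sets warn and
return empty enrichments, constant update samples report missing kurtosis,
all-identical centralities return all nodes as hubs, zero-variance genes
produce t = 0 with p = 1 rather than NaN, and graphs without self-loops are
rejected by the normalizer with instructions rather than silently producing
infinities.

## Known limitations

The moderated model assumes a single variance prior across all genes (no
robust or trend variant). The classifier's per-sample features reach every
node, so graph priors act as inductive bias rather than added information —
gains over random topologies are accordingly small on synthetic data and
should not be extrapolated to real cohorts. Hub–importance overlap on
synthetic PPI networks is near zero by construction, since random PPI edges
are independent of the planted signal; the statistic is reported for
pipeline completeness and becomes meaningful only with a real interaction
database.
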