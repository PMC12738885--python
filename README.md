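# degbrin

Cross-region differential-expression networks and an interpretable graph
convolutional classifier for three-class neurodegeneration diagnosis
(control / mild cognitive impairment / dementia) from multi-region brain
transcriptomes.

## The problem

Postmortem brain cohorts profile the same subjects across many anatomical
regions. Disease-associated transcriptional changes are regionally
heterogeneous, yet the genes that are dysregulated in *several* regions carry
the most robust signal — they trace the staged regional propagation of the
pathology. `degbrin` operationalizes that idea as a pipeline:

1. **Per-region differential expression** with an empirical-Bayes moderated
   t-statistic. For gene *g*, gene-wise residual variances are shrunk toward
   a scaled inverse-chi-square prior with hyperparameters (d₀, s₀²):

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t̃_g = β̂_g / (s̃_g · √v_g)   ~   t(d₀ + d_g)

   DEGs pass |log₂FC| > 0.585 (1.5-fold) and Benjamini–Hochberg adjusted
   p < 0.05. (d₀, s₀²) are estimated by moment matching on log s²_g.
2. **DEG-BRIN** — the brain-region interaction network. Nodes are regions;
   the universal list **G** keeps genes differentially expressed in ≥ 2
   regions; edge weights are w_ij = |G_i ∩ G_j| with self-loops
   w_ii = |G_i|.
3. **Hypergeometric enrichment** (upper tail) of DEG sets against gene-set
   collections, and **tiered PPI hub analysis**: hubs rank in the top 20% of
   both degree and betweenness centrality at confidence tiers
   τ ∈ {0.4, 0.7, 0.9}.
4. **An interpretable two-layer GCN** over the symmetric degree-normalized
   DEG-BRIN adjacency Â = D^(−1/2) W D^(−1/2):

       H⁽¹⁾ = ELU(Â H⁽⁰⁾ Θ₁),  H⁽²⁾ = ELU(Â H⁽¹⁾ Θ₂),
       z = mean over nodes of LayerNorm(H⁽²⁾),  ŷ = softmax(W_c z + b_c)

   with multiplicative softplus gates per gene and per region whose fitted
   magnitudes read directly as importances, trained with AdamW, random
   over-sampling of the minority classes (training partition only), and
   early stopping on validation loss.
5. **Interpretation**: gene/region importance rankings, parameter-update
   distribution statistics, overlap of top genes with PPI hubs, and a
   region–gene–pathway triad table.

Since no public cohort ships with the package, a first-class synthetic
cohort generator (`degbrin.simdata`) emulates the study design — 19 regions
in three pathology-stage blocks, four diagnostic strata consolidated to
CON/MCI/AD, planted DEGs with within-stage cross-region sharing, gene-wise
variances from the inverse-chi-square prior — with exact ground truth, so
every stage of the pipeline is testable end to end.

## Worked example

```python
import degbrin as db

# synthetic 19-region cohort: 30 subjects per group, planted 2-fold effects
cfg = db.SyntheticConfig(subjects_per_group={"CON": 30, "MCI": 30, "AD": 30}, seed=0)
expr, samples, truth = db.generate_cohort(cfg)

# per-region moderated-t differential expression
results = db.RegionalDGE(expr, samples).fit()
print(results.summary().head(3))
print("universal cross-region list |G| =", len(results.universal))

# DEG-BRIN and the classifier
graph = db.build_degbrin(results.region_sets)
model = db.BrainRegionGCN.from_cohort(
    expr, samples, results.region_sets, graph, feature_mode="masked", seed=0
)
fit = model.fit(seed=0)
print(fit.evaluate("test").per_class.round(2))
print("test accuracy:", round(fit.evaluate("test").accuracy, 3))
```

Output:

```
  region  MCI-CON  AD-CON  MCI-AD  union
0    R01       51      25      61     69
1    R02       44      27      55     66
2    R03       43      31      57     69
universal cross-region list |G| = 221
     precision  recall    f1
CON       0.89    0.88  0.88
MCI       0.81    0.81  0.81
AD        0.74    0.75  0.74
test accuracy: 0.813
```

The per-region table counts called DEGs per contrast (union column = the
region's DEG set); 221 genes appear in at least two regions and become both
the graph-weighting substrate and the classifier's input features. Test
accuracy is measured on a stratified 70/10/20 split with oversampling never
touching validation or test samples.

The same pipeline is available from the shell:

```bash
degbrin run --out results/demo --seed 0          # full pipeline + manifest
degbrin simulate --out data/ --seed 1            # individual stages
degbrin dge --expr data/expression.tsv --meta data/metadata.tsv --out data/
degbrin compare --expr ... --meta ... --degs data/region_sets.json --out table.tsv
```

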