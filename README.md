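# elbp

Empirical-Bayes loopy belief propagation (eLBP) for inferring **which cell
types talk to each other** — and through which ligand–receptor pairs and
upstream transcription factors — from clustered single-cell RNA-seq data.
It also ships the nine-gene **TMRS** (tumor-microenvironment risk score)
evaluator for bulk expression cohorts.

The intended user is a computational biologist who already has a clustered
count matrix (cell-type labels per cell) plus the standard curated
resources: pathway gene sets (GMT), a ligand–receptor pair table, a PPI
edge list, and TF→target sets from one or more databases.

## The method

For every cell type *k* the pipeline builds an undirected gene graph
G^k = {V^k, E^k}: nodes are the member genes of the cell type's enriched
pathways that contain at least one ligand/receptor ("communication") gene,
and edges are the PPI pairs among them. A binary Markov random field over
labels L ∈ {+1, −1} (gene present / absent in type *k*) is assembled from

* **node potentials** ψ(V_i^k) — empirical-Bayes priors from a
  Gamma–Poisson count model. Counts are Poisson(θ) with θ ~ Gamma(α, β);
  the marginal moments E(x) = α/β and Var(x) = α(1+β)/β² are inverted by
  method of moments on half of a seeded positive (≤200 cells of type *k*)
  and negative (200 other cells) reference set, and the held-out half gives
  the posterior mean rate θ̂ = mean[(x+α)/(1+β)]. The prior is the
  normalized odds ψ(+1) = θ̂₊/(θ̂₊+θ̂₋);
* **edge potentials** from the cosine similarity of the two genes'
  log-normalized expression across the type's cells, mapped to the
  agreement matrix [(1+cos)/2, (1−cos)/2].

Synchronous, damped loopy belief propagation yields per-gene beliefs
S(V_i^k) ≈ P(gene present); nodes with S < 0.7 are trimmed. Scores follow:

```
CGscore(i→j, L, R) = S(L in i) · cos(L_i, R_j) · S(R in j)     # pair strength
CTscore(i→j)       = mean CGscore over the pair's L/R genes     # type ranking
TFscore(TF, k)     = mean over regulon genes of S · cos(gene, TF)
TMRS(sample)       = Σ β_g · EXP_g                              # 9-gene model
```

TF regulons are database target sets over-represented in the trimmed
network (hypergeometric, raw p < 0.05 per source database); the gene panel
is the overlap of regulon genes with the trimmed network.

A seeded synthetic-data generator (`elbp.generate`) produces Gamma–Poisson
count bundles with a planted ligand–receptor axis between two cell types
and a planted TF co-expressed with its targets, plus ground truth, so the
whole chain is testable without any downloads.

## Worked example

```python
import elbp

bundle = elbp.generate(seed=1)                      # 300 genes x 600 cells, 3 types
result = elbp.run_pipeline(bundle.expr, bundle.gene_sets, bundle.lr,
                           bundle.ppi, bundle.tf_targets, seed=1)
print(result.interactions.ct.to_string(index=False))
print(elbp.truth_eval(result, bundle.truth))
```

prints

```
type_i type_j  ct_score  n_pairs
    T0     T1  0.957617        1
    T1     T0  0.842473        1
    T2     T1  0.841881        1
    T2     T0  0.802233        1
    T0     T2  0.800637        1
    T1     T2  0.796237        1
{'recovered': True, 'pair_rank': 1, 'n_pairs_scored': 6, 'n_tfs_scored': 4,
 'tf_rank': 1, 'panel_recall': 1.0}
```

The generator planted a boosted ligand–receptor axis from T0 to T1 and a
co-expressed TF in T0; the ordered pair (T0, T1) indeed tops the CTscore
ranking, the planted TF (G0045, TFscore 0.8765) outranks the three decoy
TFs (0.825–0.849), and every planted TF target is recovered in the T0 gene
panel. The same pipeline is exposed as a CLI
(`elbp simulate | qc | degs | enrich | run | score | tfs | panel | tmrs`).

Scoring a bulk cohort with the packaged nine-gene model:

```python
import pandas as pd
model = elbp.default_model()            # IRF1, RHOA, PLAUR, ..., VCAN
scores = elbp.tmrs_evaluate(model, bulk_df)   # samples x genes
scores.tmrs     # per-sample risk score
scores.group    # "high"/"low" by cohort-median split
```

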