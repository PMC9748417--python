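# Methods

## Model and procedure

The pipeline treats "is gene *i* meaningfully expressed in cell type *k*?"
as a binary labelling problem on a per-cell-type gene graph and solves it
approximately with loopy belief propagation (LBP), then converts the
resulting beliefs into interaction scores between cell types.

1. **QC and normalization.** Cells with total UMI strictly below 200 or
   mitochondrial fraction strictly above 35% are removed (boundary cells
   are kept). Counts are library-size scaled to 10,000 per cell and
   log1p-transformed. Both thresholds are configurable.
2. **Markers and pathways.** Per cell type, a one-vs-rest Wilcoxon
   rank-sum test on normalized values with Bonferroni adjustment
   (family-wise error control at 5%) yields positive markers. Marker
   over-representation in the supplied gene sets is tested with a
   one-sided hypergeometric test, Benjamini–Hochberg adjusted, kept at
   p_adj < 0.05; of those, pathways whose marker overlap contains at least
   one ligand or receptor gene ("communication pathways") seed the graph.
   The enrichment universe is all genes in the post-QC matrix — the usual
   conditional choice when no explicit background is given.
3. **Graph.** Nodes are the member union of the communication pathways;
   edges are PPI pairs among them (isolated nodes kept; PPI confidence
   weights carried but unused). Each edge gets the cosine similarity of
   its genes' log-normalized vectors over the type's cells. Cosines are
   computed in normalized space rather than on raw counts to damp
   library-size artifacts; an all-zero vector is assigned cosine 0, which
   makes the edge exactly uninformative under the potential map below.
4. **Empirical-Bayes priors.** Counts are modelled Poisson(θ) with
   θ ~ Gamma(shape α, rate β), whose marginal is negative binomial with
   E(x) = α/β and Var(x) = α(1+β)/β². For each graph gene and each of a
   positive reference set (≤200 cells of the type, seeded sample) and a
   negative one (200 cells outside it), the cells are split 50/50
   (seeded): one half estimates (α, β) by moment inversion
   β = m/(v−m), α = m²/(v−m); the other half gives the posterior mean rate
   as the average single-observation posterior mean (x̄+α)/(1+β) — a convex
   combination of prior mean and held-out mean, i.e. guaranteed shrinkage.
   The conjugate joint-posterior mean (Σx+α)/(n+β) is available behind
   `theta_mode="joint"`. Priors use raw counts (the likelihood is a count
   model), unlike the cosines. Genes zero in more than half of the type's
   cells are excluded from estimation and enter the MRF with a neutral
   ψ = 0.5, as does any graph gene absent from the matrix. The node prior
   is ψ(+1) = θ̂₊/(θ̂₊+θ̂₋); the −1 label gets the exact complement.
5. **MRF + LBP.** Pairwise potential for binary labels from the edge
   cosine c: (1+c)/2 on agreement, (1−c)/2 on disagreement — the canonical
   similarity→agreement map; c = 0 is uninformative, c = 1 enforces
   agreement. Messages are initialized uniform, updated synchronously
   (flooding), normalized each round, and damped
   (m ← (1−λ)·proposed + λ·old, λ = 0.5 by default); iteration stops when
   the largest message change falls below 1e-6 or after 200 rounds.
   Non-convergence returns the current beliefs with `converged=False` and
   a warning — LBP has no convergence guarantee on loopy graphs and a
   partial answer is more useful than an exception. Nodes with belief
   S < 0.7 are trimmed (S = 0.7 is kept).
6. **Scores.** CGscore = S(ligand in sender) × cross-type cosine ×
   S(receptor in receiver), computed only when both genes survive trimming
   in their respective types; CTscore is the mean CGscore of an ordered
   type pair (ordered because ligand and receptor roles are directional).
   The cross-type cosine needs a pairing rule between cells of two types:
   `subsample` (default) seed-downsamples both types to the smaller count;
   `pseudobulk` compares per-sample mean vectors over shared sample ids
   (requires ≥2 shared samples). TF regulons are database target sets
   over-represented in the trimmed network (hypergeometric raw p < 0.05,
   per source database, matching the stated selection rule; BH-adjusted
   values are reported alongside, and TFs significant in ≥2 databases are
   flagged). TFscore averages S × cos(gene, TF) over the regulon (targets
   ∩ trimmed network, not all network genes; the all-genes reading can be
   recovered by passing the full node set). The gene panel is the overlap
   of regulon genes with the trimmed network, with per-gene TF and pathway
   provenance.
7. **TMRS.** The risk score is the signed linear combination Σ β_g·EXP_g
   with a cohort-median split (ties to low). The packaged default is the
   published nine-gene coefficient vector (IRF1 −0.03085, RHOA −1.03491,
   PLAUR 0.5868, NCF2 −0.2188, CXCR4 −0.2273, HCK −0.1201, LYZ −0.1773,
   RGS1 −0.1244, VCAN 0.2259). Fitting (LASSO-Cox) is deliberately out of
   scope — any coefficient TSV can be supplied — and the expression scale
   (log vs linear) is the caller's responsibility; the coefficients are
   applied to the values as given.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_umi`, `max_mito` | 200, 0.35 | QC floors/ceilings; boundary cells kept |
| `alpha_deg`, `alpha_enrich` | 0.05 | marker FWER, pathway FDR |
| `ref_n` | 200 | reference cells per side for the priors |
| `max_zero_frac` | 0.5 | sparse-gene cut inside a type (≤ is kept) |
| `damping`, `tol`, `max_iter` | 0.5, 1e-6, 200 | LBP schedule |
| `trim_threshold` | 0.7 | belief cut; strictly-below is removed |
| `alpha_tf` | 0.05 | raw enrichment cut for TF regulons |
| `cosine_mode` | subsample | cross-type pairing rule |

## Synthetic data: what it emulates and what it does not

`elbp.generate` draws, per gene and cell, a rate θ ~ Gamma(a, μ/a) around
the gene's cell-type mean μ and a count ~ Poisson(θ) — exactly the
Gamma–Poisson family the priors assume (background genes: μ = 1, a = 4,
so E = 1, Var = 1.25). Each of the 3 cell types owns a 15-gene marker
block (μ = 4 in its home type) collected into one pathway and wired by
ring + spoke PPI edges; 10 moderately expressed TF genes and ~215
background genes complete the 300-gene default. Every ordered type pair
carries exactly one ligand–receptor pair at the same baseline strength,
so under the null all pairs are exchangeable; the planted pair
(T0 → T1) additionally multiplies its ligand and receptor means by
(1 + 4ρ).

Co-expression noise: every marker and TF gene carries an i.i.d. per-cell
Gamma(a₀, 1/a₀) activity factor (a₀ = 2) on its rate in its home type —
the same marginal law for all genes. The planted TF and its targets mix
their factors toward one shared latent factor, f = (1−ρ)·e + ρ·s, so at
ρ = 0 the planted TF is statistically exchangeable with the decoys while
at ρ = 0.9 the TF–target pairs share ≈99% of their factor variance. The
uniform background factor matters: cosine similarity of nonnegative
log-normalized vectors is dominated by mean offsets, and a co-expression
signal is only detectable against a baseline where all genes carry
comparable activity noise. ρ therefore scales both planted signals
(expression boost and factor sharing); ρ = 0 is a genuine null in which
planted-pair and planted-TF ranks are uniform over seeds.

Not emulated: doublets, ambient RNA, batch/sample effects, gene-length or
capture biases, multi-subunit receptor complexes. Passing recovery tests
show that the inference chain detects the structure it models — not that
it is robust to real-data artifacts.

Default sizes (3 types × 200 cells × 300 genes) keep a full pipeline run
around half a second, so the 20-seed recovery experiments in the test
suite finish in seconds.

## Numerical choices and degenerate inputs

* Moment inversion requires overdispersion; at v ≤ m the variance is
  clamped to m(1+1e-3) — the near-Poisson limit — and an all-zero
  reference vector yields a vanishingly small prior mean rather than an
  error, so a marker gene silent in the negative set gets ψ ≈ 1.
* Messages and beliefs are renormalized every round; an exactly-zero
  message sum falls back to uniform.
* Tie-breaks: markers sort by (p, −effect, gene); trimming keeps the
  exact-threshold node; the median TMRS sample goes to "low".
* Readers never silently drop data except documented rules (PPI
  self-loops, duplicate unordered edges, duplicate ligand–receptor rows),
  each logged with a count; score tables are written at fixed 6-decimal
  precision and round-trip exactly.

## Known limitations

* LBP accuracy degrades with loop density and coupling strength: beliefs
  match exact (enumeration) marginals to 1e-6 on trees, and to ≤0.05 on
  sparse loopy graphs (one chord) with cosines ≤ 0.7, but on dense small
  graphs with cosines near 0.9 the error versus exact marginals can reach
  ~0.3 even at convergence. This is inherent to loopy BP under strong
  attractive coupling, not an implementation artifact; the test suite
  asserts the regimes actually claimed.
* The Wilcoxon marker test stands in for the likelihood-ratio test named
  by the single-cell framework the labels come from; with Bonferroni it
  matches the 5% family-wise error criterion but not that test's exact
  p-values.
* Gene identity is case-sensitive symbol matching with no aliasing;
  resource files from mismatched genome annotations simply fail to
  overlap. Downstream warnings (edges removed for genes absent from the
  matrix, empty regulon/panel overlaps) are the symptom to watch for.
* CGscores depend on a pairing convention between cells of two types; the
  two provided modes (subsample, pseudobulk) can rank borderline pairs
  differently. The subsample mode is seeded and reproducible.
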