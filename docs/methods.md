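# Methods

`microstage` analyzes three-group (NC = healthy controls, NM = nonmetastatic
CRC, M = metastatic CRC), two-site (feces, saliva) ASV count cohorts. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic cohort does and does not emulate.

## Data model and key-ASV selection

Count tables are samples × ASVs nonnegative integer matrices; every retained
sample must have a positive library size. "Key ASVs" are those with a nonzero
count in at least ⌈n/3⌉ of a body site's samples, computed by default over
all samples of the site pooled across groups, so the three group networks
share one node set and can be compared node-for-node. A per-group variant
(threshold cleared within at least one group) is available behind
`mode="per_group"`; the pooled reading is the default because stage-wise
network comparison is the point of the pipeline.

Missing taxonomy ranks propagate as `unclassified_<parent>` so every ASV has
a label at every rank; rank-level aggregation ranks taxa by grand mean
proportion and merges everything below `top_k` into `Others`.

## SparCC basis correlations

Sequencing counts are compositional, so correlations are estimated on the
log-ratio variance scale: t_ij = Var[log(x_i/x_j)] is invariant to library
size. Under the sparsity approximation the row sums of t are linear in the
basis variances ω; solving that system gives
ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_i ω_j)), clipped to [−1, 1]. The pair with
the largest |ρ| above `exclusion_threshold` (default 0.1) is iteratively
removed from the linear system (up to `max_exclusions` = 10 rounds) because
strong pairs violate the sparsity assumption; excluded pairs still receive a
final ρ from the converged variances. Taxa with a non-positive estimated ω
are flagged and their correlations reported as missing rather than invented.

Pseudocount: each sample is closed to proportions and rescaled to a fixed
nominal depth of 10,000 before adding +1. Applying the pseudocount after
this normalization makes the estimate *exactly* invariant to per-sample
count rescaling, which a raw +1 on counts would break; the nominal depth
keeps the pseudocount's magnitude comparable to "+1 read at typical depth".

Significance: a permutation bootstrap shuffles every taxon's counts
independently across samples (destroying association, preserving marginals)
and recomputes ρ; two-sided pseudo-p-values use the add-one rule
p = (1 + #{|ρ*| ≥ |ρ̂|}) / (1 + B), so p ≥ 1/(B+1) always. Default B = 99
for desk-scale runs; 999 is recommended when edge calls at p < 0.05 must be
stable. A single deterministic estimation pass is the default; an optional
averaging mode over seeded Dirichlet resamples of each sample is provided.

## Co-occurrence networks and natural connectivity

An edge joins two key ASVs when |ρ| ≥ 0.3 **and** p < 0.05 (both defaults
configurable). Isolated key ASVs stay in the node set: the robustness
x-axis runs over all N key ASVs. Edge sign (co-occurrence vs co-exclusion)
is kept as an attribute, but the robustness statistic binarizes adjacency —
the natural-connectivity formula is defined on an unweighted adjacency
matrix, and weighting would change its closed forms.

Natural connectivity is λ̄ = ln((1/N) Σ exp(λ_i)) over the adjacency
eigenvalues — the log-average contribution of closed walks, a measure of
redundancy of alternative paths. Implementation uses `eigvalsh` plus
log-sum-exp for overflow safety; an edgeless graph gives exactly 0. The
removal curve deletes nodes one at a time to exhaustion (k = 0 … N−1),
recomputing λ̄ on the surviving subgraph with the survivor count N−k in the
normalization (the formula is a property of the current graph at each step).
The default strategy is uniform-random order averaged over seeded repeats
(100 by default; the analysis drivers and acceptance script use 30, which
is a Monte Carlo precision choice, not a model change); `degree_descending`
(static initial-degree order, ties broken by node id) is the targeted-attack
variant and is deterministic (repeats forced to 1, sd ≡ 0). Curves are
compared by trapezoidal area under mean λ̄ versus the *fraction* of nodes
removed, so groups with slightly different N remain comparable; higher AUC =
more robust.

## Bayesian source tracking (saliva → feces)

Each fecal sample (sink) is modeled as a two-component mixture: one named
source — the pooled salivary relative-abundance profile of the sink's own
disease group — plus an "unknown" source with a free Dirichlet(β) taxon
profile. Pooling the group's saliva (rather than the matched subject's) is
the default because the pipeline reports group-level summaries; per-subject
sources would be a one-line change in the panel construction.

The named profile is fixed at its β-smoothed empirical frequencies, with the
smoothing applied at count scale: (p·D₀ + β)/(D₀ + Vβ) with D₀ = 10,000.
At proportion scale a per-taxon +β would flatten the profile by a factor
1 + Vβ and systematically misattribute reads. The unknown profile is
integrated out analytically (Dirichlet-multinomial); that marginalization is
what keeps the mixture identifiable — a free unknown can imitate the sink
exactly, but pays an Occam penalty of roughly (V/2)·log(depth) nats for
doing so.

The sampler is a collapsed blocked Gibbs. Reads of the same taxon are
exchangeable, so each sweep resamples every taxon's entire saliva/unknown
split k_t from its exact conditional (binomial-coefficient ×
mixture-proportion × Dirichlet-multinomial urn terms), then draws the mixing
proportions from Dirichlet(α + totals), α = 0.001. Whole-taxon moves avoid
the rich-get-richer trap of per-read urn updates: a naive per-read (or
per-taxon binomial) sampler gets stuck in an unknown-heavy mode and
estimates pure-source sinks at ~0.5, whereas the collapsed sampler mixes in
tens of sweeps. Defaults: rarefy sinks to 1,000 reads (equal per-read weight
across samples), 100 burn-in + 100 retained sweeps, 10 restarts averaged,
β = 0.01.

"Detected" is not a property of the model, so the detection rate (fraction
of a group's fecal samples with posterior saliva proportion above a
threshold) defaults to threshold 0.001 and is always emitted alongside a
sensitivity grid {0.0001, 0.001, 0.01}.

Identifiability caveat: when the source and the true unknown community have
fully overlapping supports, the saliva fraction is only set-identified (any
f′ in an interval reproduces the sink exactly with a compensating unknown
profile). With site-structured communities — oral and gut communities
dominated by largely distinct taxa, as in this cohort — the interval
collapses and posterior means recover planted fractions within ±0.05 at
depth 2,000.

## Ordination and ANOSIM

Bray–Curtis dissimilarity on per-sample relative abundances is the default
metric (a UniFrac variant would need a phylogeny, which this data model does
not carry). PCoA eigendecomposes the Gower-centered −½·J·D²·J; all
eigenvalues are reported, including the negative ones that flag
non-Euclidean structure (Bray–Curtis routinely produces them), coordinates
use the leading positive eigenvalues, and requesting more axes than there
are positive eigenvalues is an error rather than silently padded. NMDS is
nonmetric MDS (scikit-learn, pooled-adjacent-violators monotone regression)
reporting Kruskal stress-1, best of 20 seeded starts.

ANOSIM ranks all n(n−1)/2 dissimilarities once and computes
R = (mean between-group rank − mean within-group rank)/(M/2), M = n(n−1)/2;
p is permutational with the add-one rule over 999 seeded label permutations
(floor 1/1000, matching the finest p the three-group tests report).

## Differential abundance

Pairwise contrasts use the two-sided Wilcoxon rank-sum test (exact
enumeration when both groups have ≤ 20 untied observations, tie-corrected
normal approximation otherwise); the three-group screen uses tie-corrected
Kruskal–Wallis (χ², 2 df). Taxa all-zero in the compared groups carry no
evidence and are reported as p = 1 with a flag. BH-FDR is applied within
one family per comparison per taxonomic level. Fold changes are
log2((mean_front + ε) − …) computed as a difference of logs with ε = 1e−6
on group mean proportions (exactly antisymmetric under group swap). Volcano
status uses raw p < 0.05 and |log2FC| > 1 by default, with q-driven status
behind a flag, and both p and q always emitted. Monotone screening keeps
taxa whose NC→NM→M group means are strictly monotone with Kruskal–Wallis
p < 0.05, ranked by |mean(M) − mean(NC)| per direction, truncated to top-k.

## Stage classifier

A 500-tree random forest on relative abundances of the site's key ASVs.
MeanDecreaseGini is the forest's impurity-decrease importance;
MeanDecreaseAccuracy permutes one feature at a time within each tree's
out-of-bag samples and averages the accuracy drop (the randomForest
definition, reconstructed from each tree's bootstrap seed). Performance is
stratified five-fold cross-validation with the top-8 Gini panel re-selected
inside every training fold — selecting on the full data before CV leaks test
information and inflates accuracy on null data, which a regression test
guards against (the optimistic variant is available behind
`select_in_fold=False` for comparison). All metrics are computed on pooled
out-of-fold predictions: accuracy, Cohen's κ, log loss, macro/micro F1
(micro-F1 equals accuracy for single-label multiclass), and one-vs-rest
ROC AUC per class, macro (unweighted mean over present classes) and micro
(AUC over the flattened sample × class indicator pairs — stated explicitly
because several "micro" conventions exist).

## Synthetic cohort generator

The generator emulates the study conditions: 30 subjects per group, one
fecal and one matching salivary sample each (shared subject id), multinomial
counts at depth 10,000 per sample over a shared 280-ASV vocabulary in which
120 taxa are gut-dominant and 160 saliva-dominant (off-site taxa sit at a
1e−4 relative floor, so the sites are compositionally distinct but
vocabulary-aligned).

Three signals are planted, and recorded in a ground-truth object before any
observation noise:

* **Connectivity gradient.** Latent log abundances are multivariate normal
  with unit variances; co-abundance modules are equicorrelated blocks
  (pairwise r = 0.7): feces NC {14, 10, 8} / NM {10, 8} / M {6} member taxa,
  saliva reversed. Blocks, not isolated pairs, are planted because natural
  connectivity is dominated by the leading adjacency eigenvalue: a clique of
  m recovered edges contributes e^(m−1) while scattered single edges are
  spectrally negligible against the estimation-noise edge background, so
  isolated pairs cannot realize "networks of differing connectivity" at
  n = 30. Planted covariances are Cholesky-checked; a non-positive-definite
  request fails loudly naming the offending edges.
* **Translocation gradient.** Each subject's fecal composition is
  (1−f)·gut + f·(that subject's own salivary composition), f = 0.017 / 0.032
  / 0.149 for NC / NM / M — the oral-to-gut gradient the source tracker must
  recover.
* **Differential taxa.** Six fecal taxa carry monotone log2 fold changes of
  ±1 (NM) and ±2 (M) on the latent means.

Zeros arise only from multinomial sampling (no structural zeros), keeping
prevalence controllable through depth. What the generator does **not**
emulate: sequencing-error and chimera processes, over-dispersion beyond the
log-normal/multinomial hierarchy, phylogenetic structure, longitudinal
sampling, or realistic taxonomies (the emitted taxonomy is an explicitly
synthetic stand-in). Passing tests therefore demonstrate correct parameter
recovery under the stated generative model, not performance on real
sequencing data.

## Determinism and the pipeline

Every stochastic routine takes an explicit seed (numpy `default_rng`). The
pipeline derives per-stage seeds by mixing the global seed with a CRC32 hash
of the stage name, so adding a stage never perturbs another stage's draws.
The JSON report contains no timestamps; identical config + seed reproduces
it byte-for-byte. Stage failures are recorded in the report and dependent
stages are skipped while independent stages still run.

Problem sizes in the shipped analysis drivers and acceptance script — 99
SparCC bootstraps, 30 removal-curve repeats, 10 Gibbs restarts of 100+100
sweeps at rarefaction depth 1,000 — are the package's desk-scale defaults;
each is a single config field away from larger production values.

## Known limitations

* SparCC's sparsity approximation biases basis variances when correlation
  structure is dense; the planted-module cohort keeps modules small relative
  to the table, but very dense real networks would need the averaging mode
  and more exclusion rounds.
* The source tracker supports exactly one named source plus unknown (the
  saliva→gut question); multi-source leave-one-out attribution is out of
  scope.
* ANOSIM assumes exchangeability under the null; with matched subjects
  across sites, per-site tests are valid but cross-site contrasts would need
  a restricted permutation scheme the pipeline does not implement.
* Absolute cohort numbers (key-ASV counts, ANOSIM R, detection rates,
  classifier metrics) depend on the cohort analyzed — real sequencing data
  would give different values; this package's claims are the property and
  recovery guarantees its tests compute on the synthetic cohort.
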