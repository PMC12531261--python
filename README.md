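# microstage

Stage-stratified analysis of fecal and salivary microbiomes in colorectal
cancer (CRC) progression. The package asks, for a cohort of healthy controls
(NC), nonmetastatic (NM) and metastatic (M) CRC patients with matched fecal
and salivary 16S ASV tables:

1. **Do the communities separate by stage?** Bray–Curtis ordination
   (PCoA / NMDS) with the ANOSIM permutation test.
2. **How does the ecological network change?** Per-group SparCC co-occurrence
   networks over the key ASVs (prevalence ≥ 1/3 of a site's samples), edges
   kept at |ρ| ≥ 0.3 and bootstrap p < 0.05, and network robustness measured
   as the decay of natural connectivity

       λ̄ = ln( (1/N) Σᵢ exp(λᵢ) ),   λᵢ = adjacency eigenvalues,

   under sequential node removal (higher area under the decay curve = more
   robust network).
3. **Is the gut being colonized from the mouth?** A Bayesian source tracker:
   each fecal sample is a mixture of its group's pooled salivary profile and
   an unknown source, fit by collapsed Gibbs sampling; per-group detection
   rates and mean saliva-derived fractions.
4. **Which taxa shift?** Wilcoxon / Kruskal–Wallis rank tests with BH-FDR,
   log2 fold changes, volcano classification (p < 0.05, |log2FC| > 1) and
   monotone-trend screening along NC → NM → M.
5. **Can stage be diagnosed from the community?** A three-class random
   forest on key-ASV abundances: MeanDecreaseGini / MeanDecreaseAccuracy
   rankings, top-8 Gini biomarker panels selected inside each fold of a
   stratified five-fold cross-validation, and accuracy / Cohen's κ /
   log loss / macro–micro F1 / one-vs-rest macro–micro AUC.

Because the analysis needs raw cohort data to run end-to-end, the package
ships a first-class synthetic cohort generator (`microstage.synthetic_data`)
that plants all three signals — group-specific co-abundance modules with
opposite connectivity gradients in the two sites, an oral-to-gut
translocation gradient (1.7% / 3.2% / 14.9% for NC / NM / M), and monotone
differential taxa — and records the ground truth, so every estimator is
tested by parameter recovery. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (90 + 90 samples, 280 ASVs, depth 10,000):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_ordination_anosim.py
python analysis/03_networks_robustness.py
python analysis/04_source_tracking.py
python analysis/05_differential_abundance.py
python analysis/06_stage_classifier.py
```

Selected output (what it means in brackets):

```text
feces: ANOSIM R = 0.1413, p = 0.001 (999 permutations)
    [fecal communities separate by stage; R > 0 = between-group
     dissimilarities exceed within-group]

feces: 231 key ASVs (>= 1/3 prevalence)
  NC: 1258 edges, density 0.0474, robustness AUC 3.869
  NM: 1187 edges, density 0.0447, robustness AUC 3.598
  M:  1071 edges, density 0.0403, robustness AUC 2.590
  robustness ranking (feces): NC > NM > M
    [the fecal network destabilizes as CRC progresses]
  robustness ranking (saliva): M > NM > NC
    [the salivary network does the opposite]

per-group source-tracking summary:
  NC: mean saliva fraction 0.013 (planted 0.017)
  NM: mean saliva fraction 0.025 (planted 0.032)
  M:  mean saliva fraction 0.105 (planted 0.149)
    [saliva-derived share of the fecal community rises with progression,
     recovering the planted oral-to-gut translocation gradient]

feces NM vs NC: 41 differential ASVs (38 enriched, 3 depleted)
    [volcano counts at p < 0.05 and |log2FC| > 1]

feces model (231 candidate ASVs, top-8 Gini panel):
  accuracy 82.22%, kappa 0.73, macro-AUC 92.25%, micro-AUC 93.47%
saliva model: accuracy 28.89%, kappa -0.07
    [fecal ASVs carry stage information; salivary ASVs alone do not,
     because this cohort plants its differential signal in the gut]
```

Each script writes tidy TSV/JSON tables under `results/`.

The same pipeline is scriptable from one config:

```sh
microstage run --config config.yaml --out results/run1
# or stage by stage:
microstage simulate --seed 3 --out cohort/
microstage ordinate --table cohort/feces.tsv --meta cohort/metadata.tsv \
    --method pcoa --permutations 999 --seed 3 --out results/ord
microstage network --table cohort/feces.tsv --meta cohort/metadata.tsv \
    --group NC --site feces --out results/net
microstage sourcetrack --sinks cohort/feces.tsv --sources cohort/saliva.tsv \
    --meta cohort/metadata.tsv --depth 1000 --seed 3 --out results/st
microstage classify --table cohort/feces.tsv --meta cohort/metadata.tsv \
    --topk 8 --folds 5 --trees 500 --seed 3 --out results/clf
```

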