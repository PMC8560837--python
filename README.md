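# isleprs

Polygenic-risk-score (PRS) analysis pipeline for asking how much of an
isolate population's excess disease prevalence is attributable to common risk
variants. It covers the full chain:

1. **`synthetic_cohorts`** — a generator for three case/control cohorts
   (one mainland, two island isolates) with a configurable SNP panel, a
   logistic disease model on centred dosages, optional LD blocks (Gaussian
   copula), sib-pair families (expected kinship 0.25) and covariates.
2. **`snp_panel`** — panel QC: inverse-variance meta-analysis of duplicated
   variants, p-value filtering (p < 1e-3), allele harmonisation (palindromic
   SNPs excluded) and greedy LD clumping (r² > 0.25 within ±200 kb).
3. **`prs_engine`** — weighted dosage-sum scores (ln OR weights) for the
   `full` / `no_hla` / `hla_only` subsets, z-standardised against the pooled
   distribution of all cohorts, plus control risk-allele frequencies.
4. **`association_models`** — Gaussian-error group models, genomic-kinship
   estimation and greedy unrelated-subset filtering with case protection,
   covariate-adjusted logistic regression, Nagelkerke pseudo-R², ROC/AUC
   (Hanley–McNeil SE), fixed-effect meta-analysis, genotype PCA.
5. **`population_comparison`** — Welch t-tests of control score
   distributions and per-SNP Pearson χ² frequency contrasts between cohorts.
6. **`attribution`** — the conversion calculus: control-mean score
   differences × meta-analysed beta → expected log odds-ratio; prevalence
   pairs → observed log odds-ratio; log odds-ratio → equivalent excess cases
   per 100,000 and absolute head counts (the two odds conversions are exact
   inverses).
7. **`pipeline` / `cli`** — one-config orchestration with a deterministic
   manifest.

## CLI

Run everything from the built-in synthetic scenario (three cohorts of
97/2118, 15/2090 and 30/8708 cases/controls, a 127-SNP panel with one
OR = 2.77 locus at elevated isolate frequency):

```bash
isleprs all --seed 1 --out out/
```

or stage by stage:

```bash
isleprs simulate --seed 1 --out sim/
isleprs build-panel --effects sim/panel.tsv --dosages sim/mainland.dosages.tsv --out panel.tsv
isleprs score --panel panel.tsv \
    --dosages mainland sim/mainland.dosages.tsv \
    --dosages isle_a   sim/isle_a.dosages.tsv \
    --dosages isle_b   sim/isle_b.dosages.tsv \
    --out scores.tsv
isleprs fit     --scores scores.tsv --phenotypes mainland sim/mainland.phenotypes.tsv \
                --phenotypes isle_a sim/isle_a.phenotypes.tsv \
                --phenotypes isle_b sim/isle_b.phenotypes.tsv --out models.tsv
isleprs compare --scores scores.tsv --phenotypes mainland sim/mainland.phenotypes.tsv \
                --phenotypes isle_a sim/isle_a.phenotypes.tsv \
                --phenotypes isle_b sim/isle_b.phenotypes.tsv --out comparison.tsv
isleprs attribute --comparison comparison.tsv --model-report models.tsv \
                  --prevalence prev.tsv --baseline mainland --out attribution.tsv
```

A YAML config (see `isleprs.pipeline.RunConfig`) can point the same pipeline
at file-based cohorts: dosages as TSV (rows = individuals) or VCF 4.2 with a
`DS` FORMAT field, phenotypes as TSV `id status age sex pc1 pc2`, the panel
as TSV `rsid chrom pos risk_allele other_allele or p source`, and observed
prevalences as TSV `population prevalence_per_1e5 population_size`.

Note: kinship filtering defaults to off in the pipeline because a ~100-SNP
scoring panel is far too sparse to estimate genomic kinship at a 0.05
threshold (sampling SD ≈ 0.04); enable `kinship_enabled` only with
genome-wide dosage input.

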