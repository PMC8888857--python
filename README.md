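# pathprs

Genome-wide and pathway-specific polygenic risk scores (PRS) for
case/control traits, by LD clumping + p-value thresholding (C+T), with a
fully synthetic two-cohort study design for testing every stage without
access to individual-level data.

## The scientific problem

Hypertension (like most common diseases) is highly polygenic: thousands of
variants of tiny effect jointly shift an individual's liability. A PRS
collapses a base GWAS into one number per person,

```
PRS_i(t) = Σ_{j : p_j ≤ t}  β_j · g_ij
```

where `β_j` and `p_j` are the base-GWAS effect (per effect allele) and
p-value of variant `j`, `g_ij` is individual `i`'s effect-allele dosage,
and the sum runs over LD-clumped index variants passing a p-value
threshold `t`. Clumping keeps, per LD region, only the most significant
variant: greedily take the unassigned variant with the smallest `p` as an
index and absorb all unassigned variants within ±250 kb having r² > 0.1
with it, each variant belonging to at most one clump.

The score is evaluated in an independent target cohort by logistic
regression of case status on the standardized PRS plus covariates (sex,
BMI and the first 4 principal components; age is excluded because the
extreme ascertainment — cases with onset before 50, never-treated
normotensive "hyper-normal" controls older than 50 — makes it bimodal and
confounded with status). Reported are:

- **partial Nagelkerke pseudo-R²** — `R²_N(full) − R²_N(covariates)`,
  with `R²_N = R²_CS / (1 − exp(2·llnull/n))` and
  `R²_CS = 1 − exp(−2(ll − llnull)/n)`; the threshold grid
  `(1, 0.5, 0.05, 1e-4, 1e-6, 5e-8)` is scanned and the best model kept;
- **decile odds ratios** — individuals stratified by PRS deciles, each
  decile's case/control 2×2 table compared against the median decile
  (crude cross-product OR, Wald 95% CI);
- **ROC/AUC with DeLong's paired test** comparing the full model against
  the covariates-only model;
- **pathway-specific PRS** — variants mapped to genes by coordinates
  (intergenic variants excluded), a *full* (no p-value filter) clumped
  score per gene set, Wald z = β/SE per pathway, BH-FDR across pathways,
  and a **competitive empirical p**: the pathway's association p is
  compared against `n_perm` size-matched random draws of k variants from
  the post-clumping genic background,
  `p_comp = (#{p_perm ≤ p_obs} + 1)/(n_perm + 1)`;
- **cross-cohort concordance** — Pearson correlation of pathway z-scores
  between the target and a validation cohort that re-scores the
  target-fitted variant lists and weights.

## Layout

- `src/pathprs/` — the library: `syndata` (simulator), `io` (TSV/VCF/BED/
  GMT readers), `harmonize` (allele orientation, QC, PCs), `clumpscore`
  (LD, clumping, threshold scan), `assoc` (logistic fits, Nagelkerke R²,
  deciles, ROC/DeLong), `pathway` (gene mapping, competitive permutation),
  `pipeline` (orchestration), `cli`.
- `analysis/` — numbered narrative drivers writing tables under
  `results/` (data bundles go to `scratch/`, which is disposable).
- `docs/methods.md` — model, parameter and design documentation.

## Worked example

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_genomewide_prs.py
python analysis/03_pathway_prs.py
python analysis/04_published_decile_ors.py
```

At the default scale (2,000 individuals per cohort before ascertainment,
5,000 variants in 100 LD blocks, 250 causal variants explaining 30% of
liability variance, one planted causal-enriched pathway among 40),
script 02 prints:

```
[target] best threshold p<=1 (100 variants): partial R2 = 10.97%, assoc p = 8.90e-21, AUC 0.595 -> 0.689 (DeLong p = 4.80e-08)
          top-vs-median decile OR = 2.73 [1.60, 4.68]
[validation] best threshold p<=1 (100 variants): partial R2 = 12.94%, assoc p = 2.49e-24, AUC 0.595 -> 0.701 (DeLong p = 2.43e-09)
          top-vs-median decile OR = 3.96 [2.29, 6.82]
```

i.e. the PRS explains ~11% of liability beyond sex+BMI+PCs, lifts the AUC
from 0.60 to 0.69, and individuals in the top PRS decile have ~3-4× the
odds of being a case relative to the median decile. Script 03 then shows
the planted pathway dominating the competitive ranking
(`pathway0001: z = 8.2, p_comp = 0.002`, the permutation floor at 500
draws) while the remaining pathways' competitive p-values spread towards
uniformity, and a cross-cohort z-score concordance of r = 0.67.

The same pipeline is scriptable from the shell:

```sh
pathprs simulate --out demo --seed 1
pathprs run-all --config demo/config.yaml
```

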