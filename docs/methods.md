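# Methods

## Scope and model

`pathprs` implements clumping+thresholding polygenic scores for a binary
trait, their evaluation in ascertained case/control cohorts, and
pathway-specific scores with a competitive permutation null. All
statistics operate on three inputs: base GWAS summary statistics
(per-variant effect allele, β, p), target genotypes (effect-allele
dosages 0–2), and a phenotype/covariate table. A synthetic-data module
generates all three with known ground truth, so every claim the test
suite makes is checked against a generative model rather than against
convenience fixtures.

## Harmonization

Variants are matched between base statistics and target panel by
(chromosome, position); rsID dialects are deliberately ignored. The base
effect allele is reconciled with the target REF/ALT pair directly or via
strand complement; when the effect allele is the target REF, the record
is flagged and scored as `2 − dosage`. Palindromic variants (A/T, C/G)
are always dropped: without allele-frequency information their strand is
undecidable, and no frequency-based rescue is attempted. Duplicate
records at one position are resolved by exact allele-pair match, else
dropped. QC removes variants below a MAF or call-rate cutoff (defaults
0.01 and 0.95 — explicit configuration, not a claim about any particular
study) and mean-imputes remaining missing dosages, the conventional C+T
choice; the filter is idempotent.

Principal components are computed from the column-standardized dosage
matrix by exact SVD, ordered by explained variance, with the sign fixed
so each component's largest-magnitude variant loading is positive —
outputs are therefore comparable across runs and platforms.

## Clumping and scoring

Greedy p-value-ordered clumping: the unassigned variant with the
smallest p becomes an index; unassigned variants on the same chromosome
within ±`window` (default 250 kb, read as flanking distance) and with
r² > `r2_max` (default 0.1, strictly greater; boundary r² is retained)
are absorbed into its clump. Ties on p are broken by (chromosome,
position) so runs are deterministic. LD is the squared Pearson
correlation of dosage vectors computed on the target cohort's own
genotypes; the validation cohort never re-clumps — it re-scores the
target-derived variant list and weights, which is what "applying the
model" means for a C+T score.

The score is the raw weighted sum of effect-allele dosages (no allele
count normalisation). Downstream regressions standardize it within
cohort, so its scale affects neither p-values nor decile membership.
Swapping which allele the base study calls "effect" shifts the raw score
by the constant `2β` per flipped variant; all reported quantities are
invariant to that shift.

## Association statistics

Logistic fits go through statsmodels (maximum likelihood, convergence
and separation failures raised, never silently returned). Nagelkerke
pseudo-R² uses the likelihood-ratio Cox–Snell form rescaled to a [0,1]
maximum; the "partial" R² is the full-model minus covariate-only value
against a common intercept-only null. Decile ORs are crude cross-product
ratios of each decile's 2×2 table against the median decile with Wald
CIs (SE = √Σ1/cell); zero cells receive a 0.5 continuity correction and
are flagged. Covariate-adjusted per-decile estimates would require
individual-level covariates, which per-decile counts do not carry — the
published count tables can therefore only be reproduced where the
printed OR is itself crude, and the analysis script flags exactly those
rows. ROC AUC uses the mid-rank tie convention; DeLong's paired test is
computed from placement values, with the covariance of the two models'
placements across cases and controls giving var(ΔAUC); identical
predictions return p = 1 and a degeneracy flag. ROC model predictions
are in-sample fitted probabilities, matching the single-cohort
comparison being made; no cross-validated AUC is claimed.

## Pathway scores and the competitive null

A variant belongs to a gene iff its 1-based position lies inside the
BED 0-based half-open interval; variants in no gene are excluded and the
rest form the genic background; a variant inside several overlapping
genes belongs to all of them, but is counted once per pathway. Pathway
scores are full models (threshold 1.0) after clumping restricted to the
set's variants, because small sets cannot afford p-value filtering.
Self-contained significance is the covariate-adjusted Wald z = β/SE.

The competitive permutation draws k variants (k = the pathway's
post-clumping variant count) uniformly without replacement from the
genic variants that survived *genome-wide* clumping, scores them with
their base-GWAS weights, and records the association p; the empirical p
uses the standard +1 correction, so its floor is 1/(n_perm+1). Sampling
from the post-clumping background keeps permuted set sizes comparable to
the observed one without re-clumping every draw; size matching is on
variant count only (no MAF or LD matching). Re-clumping per draw is not
offered: it would change what "k variants" means between the observed
set and its null draws.

The permutation inner loop uses an in-package warm-started
Newton–Raphson logistic solver started at the covariate-only MLE; it
reaches the same maximum likelihood as statsmodels (asserted to 1e-6 by
the test suite) at a fraction of the per-fit overhead, which is what
makes 10⁴ permutations per pathway feasible. Non-convergent permutation
fits are recorded as p = 1, a conservative choice that can only inflate
the competitive p.

FDR is Benjamini–Hochberg across tested pathways. Replication requires
FDR q < 0.05 in both cohorts with concordant effect direction.
Cross-cohort concordance is the Pearson correlation of paired pathway
z-scores with a Fisher-z 95% CI.

## The synthetic-data generator

The generator emulates the study design the statistics are built for,
not human population genetics:

- **Genotypes.** Variants sit in fixed-size blocks; within a block a
  latent Gaussian AR(1) process is discretised at Hardy–Weinberg
  quantiles (a Gaussian copula). Discretisation attenuates correlation,
  so the AR coefficient between adjacent variants is de-attenuated by
  the first Hermite coefficient of the threshold function,
  `a(p) = (φ(q₀)+φ(q₁))/√(2p(1−p))`; `within_block_corr` (default 0.8)
  thus targets the *genotype* correlation, capped by the
  allele-frequency bound exactly as real LD is. Blocks are mutually
  independent; there is no recombination-distance decay beyond AR(1),
  no population structure, and no relatedness — so passing tests say
  nothing about stratification robustness beyond what the PC covariates
  are given to correct.
- **Base GWAS.** `β̂_j ~ N(β_j, SE_j²)` with the large-sample balanced
  case/control SE, `SE_j = 1/√(n·2p_j(1−p_j)·0.25)`, at a biobank-scale
  default n = 458,554; p-values are two-sided Wald. The reported effect
  allele is REF or ALT with equal probability, and ~5% of variants are
  palindromic, so harmonization is always exercised.
- **Phenotypes.** liability = √h²·G* + √(1−h²)·E*, with G* the
  standardized true genetic score (default 250 causal variants, effects
  N(0, 0.05²), h² = 0.3) and E* the standardized sum of sex and BMI
  effects plus Gaussian noise, orthogonalized against G* so the
  in-sample genetic variance share equals h² exactly. Case status is
  liability above the (1 − prevalence) quantile (prevalence 0.45).
  Hypertensives draw an onset age ~ U(28, 70) and enter as cases only if
  onset < 50; normotensives draw an age ~ U(35, 75) and enter as
  controls only if older than 50; the rest are discarded. This yields a
  ~40/60 case/control cohort of ~1,150 from 2,000 simulated individuals,
  a bimodal age distribution, and genetically depleted ("hyper-normal")
  controls — the enrichment of protective alleles that extreme-control
  designs rely on.
- **Annotation.** Non-overlapping gene intervals tile the panel so that
  70% of variants are genic by default; 40 pathways of 8–25 genes are
  drawn with sharing across sets. One planted pathway receives 75% of
  the causal variants and its genes are made exclusive to it: with
  shared genes the planted signal leaks into other sets and the study no
  longer contains *one* enriched pathway, which is the scenario the demo
  is meant to instantiate.
- **Validation cohort.** Independent individuals drawn on the same
  variant panel (same positions, alleles, frequencies, LD law), sharing
  the true model — the idealisation of two cohorts imputed to a common
  reference.

Everything derives from one integer seed fanned out to per-stage child
seeds through a fixed SeedSequence rule; identical seed and configuration
give byte-identical output files.

## Problem sizes and numerical choices

The default study scale (2,000 × 5,000 per cohort, 40 pathways, 500
permutations) keeps a full two-cohort analysis around half a minute and
the replicate-based test suite within minutes, while leaving every
statistic far from small-sample degeneracy. The permutation count in the
shipped analyses (500) puts the empirical-p floor at ~0.002; the
`n_perm` flag raises it to the 10⁴ used for publication-grade empirical
p-values. Logistic convergence tolerance is 1e-10 on the log-likelihood
with a 1e-8 step criterion; standard errors above 10³ are treated as
quasi-separation. Thresholded comparisons of r² against `r2_max` are
strict inequalities; instances with r² at the boundary to machine
precision are knife-edge by construction and excluded from oracle
equivalence tests.

## Known limitations

- LD is blockwise AR(1); there are no long-range LD artefacts, no MHC-like
  regions, and clumping window behaviour is only exercised up to the
  simulated span.
- The competitive null matches on variant count only; real pathway
  analyses may additionally match MAF/LD profiles.
- Decile ORs are crude by design; adjusted per-decile estimates are
  available from the logistic machinery but are not the primary surface.
- In-sample AUCs overstate out-of-sample discrimination; the validation
  cohort mitigates but does not eliminate this (weights remain
  base-GWAS-derived).
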