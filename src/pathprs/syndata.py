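"""Synthetic cohort generator: LD-block genotypes, base GWAS summary
statistics, liability-model phenotypes with extreme case/control
ascertainment, and gene/pathway annotations.

The generator emulates the study design this pipeline is built for: a
large base GWAS provides per-variant effect estimates, while the target
cohort consists of early-onset hypertensive cases and "hyper-normal"
controls — normotensive individuals past the age by which most
genetically susceptible people have converted, an ascertainment that
enriches protective alleles among controls.

LD model: within fixed-size blocks a latent Gaussian AR(1) process is
discretised into genotype classes at Hardy-Weinberg quantiles (a Gaussian
copula); blocks are mutually independent. This reproduces the block-wise
r² decay that clumping exploits without simulating recombination.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pathprs.containers import GenotypeData, TrueModel

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "draw_true_model",
    "simulate_base_gwas",
    "simulate_phenotype",
    "simulate_annotation",
    "simulate_validation_genotypes",
    "write_vcf",
    "write_sumstats",
    "write_pheno",
    "write_bed",
    "write_gmt",
    "AscertainmentError",
]

# Non-palindromic REF/ALT pairs (a palindromic pair is its own reverse
# complement — A/T or C/G — and cannot be strand-resolved downstream).
_SAFE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
               ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AscertainmentError(RuntimeError):
    """No individual satisfies the case or control eligibility rule."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the demonstration scale: 2,000 individuals by 5,000
    variants in 100 LD blocks, 250 causal variants explaining 30% of
    liability variance, cases ascertained for onset before 50 and controls
    for being normotensive past 50.
    """

    n_individuals: int = 2000
    n_variants: int = 5000
    n_blocks: int = 100
    within_block_corr: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 250
    effect_sd: float = 0.05
    heritability_target: float = 0.3
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.25, "bmi": 0.10}
    )
    prevalence: float = 0.45
    case_def_age: float = 50.0
    control_min_age: float = 50.0
    frac_palindromic: float = 0.05
    missing_rate: float = 0.0
    n_chromosomes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("n_individuals and n_variants must be positive")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not (0 <= self.heritability_target < 1):
            raise ValueError("heritability_target must lie in [0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_blocks < 1 or self.n_blocks > self.n_variants:
            raise ValueError("n_blocks must lie in [1, n_variants]")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _make_variant_panel(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant metadata: positions, alleles, MAFs and block assignment."""
    m = config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    chrom_of = np.repeat(
        np.arange(1, config.n_chromosomes + 1),
        np.diff(np.linspace(0, m, config.n_chromosomes + 1).astype(int)),
    )
    # intervariant spacing ~U(500, 1500) bp, restarting per chromosome
    gaps = rng.integers(500, 1500, size=m)
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, config.n_chromosomes + 1):
        mask = chrom_of == c
        pos[mask] = 10_000 + np.cumsum(gaps[mask])

    block_of = np.minimum(
        np.arange(m) // int(np.ceil(m / config.n_blocks)), config.n_blocks - 1
    )

    is_palindromic = rng.random(m) < config.frac_palindromic
    safe = rng.integers(0, len(_SAFE_PAIRS), size=m)
    pal = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    safe_ref = np.array([_SAFE_PAIRS[i][0] for i in safe])
    safe_alt = np.array([_SAFE_PAIRS[i][1] for i in safe])
    pal_ref = np.array([_PALINDROMIC_PAIRS[i][0] for i in pal])
    pal_alt = np.array([_PALINDROMIC_PAIRS[i][1] for i in pal])
    ref = np.where(is_palindromic, pal_ref, safe_ref)
    alt = np.where(is_palindromic, pal_alt, safe_alt)

    return pd.DataFrame(
        {
            "SNP": [f"snp{i + 1:06d}" for i in range(m)],
            "CHR": chrom_of.astype(str),
            "BP": pos,
            "REF": ref,
            "ALT": alt,
            "MAF": mafs,
            "BLOCK": block_of,
        }
    )


def _dosage_latent_corr(p: np.ndarray) -> np.ndarray:
    """corr(dosage, latent z) for the HWE three-class discretisation.

    First Hermite coefficient of the threshold function over its SD:
    (φ(q0) + φ(q1)) / sqrt(2p(1-p)). Used to de-attenuate the latent
    AR(1) coefficient so ``within_block_corr`` targets the *genotype*
    correlation (achievable only up to the allele-frequency bound; rare
    variants cap below it, as LD between frequency-mismatched variants
    does in real data).
    """
    q0 = stats.norm.ppf((1.0 - p) ** 2)
    q1 = stats.norm.ppf((1.0 - p) ** 2 + 2.0 * p * (1.0 - p))
    return (stats.norm.pdf(q0) + stats.norm.pdf(q1)) / np.sqrt(2.0 * p * (1.0 - p))


def _draw_dosages(panel: pd.DataFrame, n: int, rho: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian-copula dosages: AR(1) latent per block, HWE thresholds."""
    m = len(panel)
    p = panel["MAF"].to_numpy()
    block = panel["BLOCK"].to_numpy()
    chrom = panel["CHR"].to_numpy()

    a = _dosage_latent_corr(p)
    z = np.empty((n, m))
    eps = rng.standard_normal((n, m))
    for j in range(m):
        new_block = j == 0 or block[j] != block[j - 1] or chrom[j] != chrom[j - 1]
        if new_block or rho == 0.0:
            z[:, j] = eps[:, j]
        else:
            rho_j = min(rho / (a[j - 1] * a[j]), 0.999)
            z[:, j] = rho_j * z[:, j - 1] + np.sqrt(1.0 - rho_j**2) * eps[:, j]

    # HWE genotype-class cutpoints on the standard normal scale
    q0 = stats.norm.ppf((1.0 - p) ** 2)
    q1 = stats.norm.ppf((1.0 - p) ** 2 + 2.0 * p * (1.0 - p))
    dosage = (z > q0).astype(np.float32) + (z > q1).astype(np.float32)
    return dosage


def simulate_genotypes(config: SimulationConfig) -> GenotypeData:
    """Generate an LD-block-structured cohort genotype matrix.

    Deterministic in ``config.seed``; positions strictly increase within
    each chromosome; dosages are hard calls in {0,1,2} (NaN where
    ``missing_rate`` masks calls).
    """
    rng = _rng(config.seed)
    panel = _make_variant_panel(config, rng)
    dosage = _draw_dosages(panel, config.n_individuals, config.within_block_corr, rng)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    samples = [f"ind{i + 1:05d}" for i in range(config.n_individuals)]
    return GenotypeData(dosages=dosage, variants=panel, samples=samples)


def simulate_validation_genotypes(config: SimulationConfig, genotypes: GenotypeData,
                                  n_individuals: int, seed: int) -> GenotypeData:
    """Independent individuals drawn on the *same* variant panel.

    Reuses positions, alleles and allele frequencies so a model trained in
    one cohort transfers variant-for-variant to the other, as when two
    cohorts are imputed to a common reference.
    """
    rng = _rng(seed)
    dosage = _draw_dosages(genotypes.variants, n_individuals, config.within_block_corr, rng)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    samples = [f"val{i + 1:05d}" for i in range(n_individuals)]
    return GenotypeData(dosages=dosage, variants=genotypes.variants.copy(), samples=samples)


def draw_true_model(variant_table: pd.DataFrame, n_causal: int, effect_sd: float,
                    seed, candidate_ids=None, candidate_frac: float = 0.0) -> TrueModel:
    """Draw causal variants and their per-allele liability effects.

    ``candidate_ids`` with ``candidate_frac`` > 0 concentrates that
    fraction of causal variants inside a designated subset (used to plant
    an enriched pathway); the rest are scattered uniformly elsewhere.
    """
    rng = _rng(seed)
    all_ids = variant_table["SNP"].to_numpy()
    if n_causal > len(all_ids):
        raise ValueError("n_causal exceeds panel size")
    if candidate_ids is not None and candidate_frac > 0:
        candidate_ids = [s for s in candidate_ids if s in set(all_ids)]
        n_in = min(int(round(candidate_frac * n_causal)), len(candidate_ids))
        chosen_in = rng.choice(candidate_ids, size=n_in, replace=False)
        pool = np.setdiff1d(all_ids, chosen_in)
        chosen_out = rng.choice(pool, size=n_causal - n_in, replace=False)
        causal = np.concatenate([chosen_in, chosen_out])
    else:
        causal = rng.choice(all_ids, size=n_causal, replace=False)
    causal = np.sort(causal)
    betas = rng.normal(0.0, effect_sd, size=n_causal)
    return TrueModel(causal_ids=list(causal), true_betas=betas)


def simulate_base_gwas(genotypes: GenotypeData, true_model: TrueModel,
                       n_base: int, seed) -> pd.DataFrame:
    """Base GWAS summary statistics: true effects plus sampling noise.

    Per-variant standard error follows the large-sample form for a
    balanced case/control logistic GWAS, SE_j = 1 / sqrt(n * 2 p_j (1-p_j)
    * 0.25); the estimate is beta_hat ~ N(true_beta, SE²) and the p-value
    is the two-sided Wald p. The reported effect allele (A1) is chosen
    uniformly between REF and ALT per variant, with the beta sign adjusted,
    so downstream harmonisation is always exercised.
    """
    if n_base < 2:
        raise ValueError("n_base must be at least 2")
    rng = _rng(seed)
    panel = genotypes.variants
    p = panel["MAF"].to_numpy() if "MAF" in panel else np.clip(
        np.nanmean(genotypes.dosages, axis=0) / 2.0, 1e-3, 1 - 1e-3)
    se = 1.0 / np.sqrt(n_base * 2.0 * p * (1.0 - p) * 0.25)

    beta_alt = true_model.beta_vector(panel)
    beta_hat = beta_alt + rng.normal(0.0, se)
    zval = beta_hat / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(zval)), 1e-300, 1.0)

    effect_is_alt = rng.random(len(panel)) < 0.5
    a1 = np.where(effect_is_alt, panel["ALT"], panel["REF"])
    a2 = np.where(effect_is_alt, panel["REF"], panel["ALT"])
    beta_rep = np.where(effect_is_alt, beta_hat, -beta_hat)

    return pd.DataFrame(
        {
            "SNP": panel["SNP"],
            "CHR": panel["CHR"],
            "BP": panel["BP"],
            "A1": a1,
            "A2": a2,
            "BETA": beta_rep,
            "P": pval,
        }
    )


def simulate_phenotype(genotypes: GenotypeData, true_model: TrueModel,
                       config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Liability-threshold phenotypes with early-onset / hyper-normal ascertainment.

    liability = sqrt(h²)·G* + sqrt(1−h²)·E*, where G* is the standardized
    true genetic score and E* the standardized sum of covariate effects
    (sex, BMI) and Gaussian noise; an individual is hypertensive when
    liability exceeds the (1 − prevalence) quantile. Hypertensives receive
    an onset age ~ U(28, 70) and enter the cohort as cases only when onset
    < ``case_def_age``; normotensives receive a current age ~ U(35, 75)
    and enter as controls only when older than ``control_min_age``.
    Everyone else is discarded. Returns the ascertained cohort table
    (IID, STATUS, SEX, BMI, AGE) plus ground-truth columns LIABILITY and
    G_TRUE for recovery tests; ``true_model.liability`` is filled with the
    full pre-ascertainment vector.
    """
    if seed is None:
        seed = config.seed + 104729  # fixed offset: phenotype stream independent of genotypes
    rng = _rng(seed)
    n = genotypes.n_samples

    beta = true_model.beta_vector(genotypes.variants)
    dos = np.nan_to_num(genotypes.dosages, nan=0.0)
    g = dos @ beta.astype(np.float32)
    g = np.asarray(g, dtype=float)
    g_std = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(n)

    sex = rng.integers(0, 2, size=n)  # 1 = male
    bmi = rng.normal(26.5, 3.5, size=n)
    eff = config.covariate_effects
    env = (
        eff.get("sex", 0.0) * (sex - sex.mean())
        + eff.get("bmi", 0.0) * (bmi - bmi.mean()) / bmi.std()
        + rng.standard_normal(n)
    )
    # orthogonalize against the genetic score so the in-sample genetic
    # share of liability variance equals heritability_target exactly
    env = env - env.mean()
    if g.std() > 0:
        env = env - (env @ g_std) / n * g_std
    env_std = env / env.std()

    h2 = config.heritability_target
    liability = np.sqrt(h2) * g_std + np.sqrt(1.0 - h2) * env_std
    true_model.liability = liability
    true_model.genetic_score = g

    hypertensive = liability > np.quantile(liability, 1.0 - config.prevalence)

    onset_age = rng.uniform(28.0, 70.0, size=n)
    current_age = rng.uniform(35.0, 75.0, size=n)
    age = np.where(hypertensive, onset_age, current_age)

    is_case = hypertensive & (onset_age < config.case_def_age)
    is_control = ~hypertensive & (current_age > config.control_min_age)
    keep = is_case | is_control
    if not keep.any():
        raise AscertainmentError("no individual meets the case or control definition")
    if not is_case.any() or not is_control[keep].any():
        raise AscertainmentError("ascertainment produced a single-class cohort")

    cohort = pd.DataFrame(
        {
            "IID": np.asarray(genotypes.samples)[keep],
            "STATUS": is_case[keep].astype(int),
            "SEX": sex[keep],
            "BMI": bmi[keep],
            "AGE": age[keep],
            "LIABILITY": liability[keep],
            "G_TRUE": g[keep],
        }
    )
    return cohort


def simulate_annotation(variant_table: pd.DataFrame, n_genes: int, n_pathways: int,
                        pathway_size_range: tuple[int, int], frac_intergenic: float,
                        seed) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Gene intervals (BED convention) and pathway gene sets.

    Genes are non-overlapping intervals tiling the variant panel so that a
    fraction ``1 - frac_intergenic`` of variants falls inside a gene;
    pathways draw genes with replacement across sets (genes can be shared
    between pathways, as in curated pathway databases).

    Returns ``(gene_bed, gene_sets)`` with ``gene_bed`` columns
    CHR/START/END/GENE (0-based half-open) and ``gene_sets`` mapping
    pathway name -> member gene list.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = pathway_size_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid pathway_size_range")
    if hi > n_genes:
        raise ValueError("pathway_size_range exceeds n_genes")
    if not (0 <= frac_intergenic < 1):
        raise ValueError("frac_intergenic must lie in [0, 1)")

    rng = _rng(seed)
    rows = []
    gene_id = 0
    for chrom, sub in variant_table.groupby("CHR", sort=False):
        pos = sub["BP"].to_numpy()
        m = len(pos)
        genes_here = max(1, int(round(n_genes * m / len(variant_table))))
        bounds = np.linspace(0, m, genes_here + 1).astype(int)
        for a, b in zip(bounds[:-1], bounds[1:]):
            run = b - a
            if run == 0:
                continue
            n_in = int(round(run * (1.0 - frac_intergenic)))
            if n_in == 0:
                continue
            offset = int(rng.integers(0, run - n_in + 1))
            first, last = a + offset, a + offset + n_in - 1
            gene_id += 1
            rows.append(
                {
                    "CHR": chrom,
                    "START": int(pos[first]) - 1,  # BED 0-based start
                    "END": int(pos[last]),  # half-open end covers pos[last]
                    "GENE": f"gene{gene_id:05d}",
                }
            )
    gene_bed = pd.DataFrame(rows)

    gene_names = gene_bed["GENE"].to_numpy()
    gene_sets: dict[str, list[str]] = {}
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_names, size=min(size, len(gene_names)), replace=False)
        gene_sets[f"pathway{k + 1:04d}"] = sorted(members)
    return gene_bed, gene_sets


# ---------------------------------------------------------------------------
# plain-text writers for the standard interchange formats
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeData, path, dosage_field: bool = False) -> None:
    """Write a VCF 4.2 text file with GT (hard calls) or DS (dosages)."""
    panel = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosage_field:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom, sub in panel.groupby("CHR", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['BP'].max()) + 10_000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        fmt = "GT:DS" if dosage_field else "GT"
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(genotypes.n_variants):
            row = panel.iloc[j]
            calls = []
            for d in genotypes.dosages[:, j]:
                if np.isnan(d):
                    calls.append("./." + (":." if dosage_field else ""))
                    continue
                gt = gt_codes[int(round(d))]
                calls.append(f"{gt}:{d:.3f}" if dosage_field else gt)
            fh.write(f"{row['CHR']}\t{row['BP']}\t{row['SNP']}\t{row['REF']}\t"
                     f"{row['ALT']}\t.\tPASS\t.\t{fmt}\t" + "\t".join(calls) + "\n")


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats.to_csv(path, sep="\t", index=False,
                    columns=["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"])


def write_pheno(cohort: pd.DataFrame, path) -> None:
    out = cohort[["IID", "STATUS", "SEX", "BMI", "AGE"]].copy()
    out["BMI"] = out["BMI"].round(3)
    out["AGE"] = out["AGE"].round(2)
    out.to_csv(path, sep="\t", index=False)


def write_bed(gene_bed: pd.DataFrame, path) -> None:
    gene_bed.to_csv(path, sep="\t", index=False, header=False,
                    columns=["CHR", "START", "END", "GENE"])


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write(name + "\tsynthetic\t" + "\t".join(genes) + "\n")


def replace(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return dataclasses.replace(config, **kwargs)
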