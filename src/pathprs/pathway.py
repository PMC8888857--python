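"""Pathway-specific polygenic scores and competitive permutation tests.

Variants are mapped to genes by coordinate overlap (exonic and intronic
alike; intergenic variants are excluded, forming the genic background).
Each pathway's PRS is a full model — clumping restricted to the set's
variants, then no p-value filtering — so small sets keep their whole
signal. Self-contained significance is the covariate-adjusted logistic
Wald test of the set's PRS (z = beta/SE); competitive significance asks
whether that association beats size-matched random draws of k variants
from the genic background, with the standard +1 permutation correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pathprs import assoc
from pathprs.clumpscore import ClumpParams, clump, score
from pathprs.containers import ClumpResult, GenotypeData, HarmonizedPanel

logger = logging.getLogger(__name__)

__all__ = ["map_snps_to_genes", "geneset_snps", "pathway_score",
           "self_contained_test", "fdr_adjust", "PermutationBackground",
           "make_background", "competitive_p", "ConcordanceResult",
           "concordance", "replication_filter", "run_pathway_analysis"]


def map_snps_to_genes(variants: pd.DataFrame, gene_bed: pd.DataFrame) -> dict[str, list[str]]:
    """Map variants to genes by position; intergenic variants are excluded.

    Gene intervals follow the BED convention (0-based half-open), variant
    positions are 1-based, so a variant with position p lies in
    [start, end) iff start < p <= end. A variant inside several
    overlapping genes maps to all of them.
    """
    mapping: dict[str, list[str]] = {}
    for chrom, genes_c in gene_bed.groupby("CHR", sort=False):
        sub = variants[variants["CHR"].astype(str) == str(chrom)]
        if sub.empty:
            continue
        pos = sub["BP"].to_numpy()
        ids = sub["SNP"].to_numpy()
        for g in genes_c.itertuples(index=False):
            inside = (pos > g.START) & (pos <= g.END)
            for snp in ids[inside]:
                mapping.setdefault(snp, []).append(g.GENE)
    if not mapping:
        raise ValueError("no variant overlaps any gene interval "
                         "(coordinate convention or build mismatch?)")
    return mapping


def geneset_snps(genes, snp_to_genes: dict[str, list[str]]) -> list[str]:
    """Variants mapped into any member gene (each counted once)."""
    members = set(genes)
    return [snp for snp, gs in snp_to_genes.items() if members.intersection(gs)]


def pathway_score(snp_ids, panel: HarmonizedPanel, genotypes: GenotypeData,
                  clump_params: ClumpParams | None = None):
    """Full-model PRS of one gene set: clump within the set, score at p ≤ 1.

    Returns ``(scores, clump_result)`` where scores is a per-individual
    Series and the clump result records which variants the set retained.
    """
    sub = panel.variants[panel.variants["SNP"].isin(set(snp_ids))]
    if sub.empty:
        raise ValueError("gene set maps to no harmonized variant")
    sub_panel = HarmonizedPanel(variants=sub)
    cres = clump(sub_panel, genotypes, clump_params)
    profile = score(genotypes, cres, thresholds=(1.0,))
    return profile.scores[1.0], cres


def _adjusted_prs_fit(y: np.ndarray, X_cov: np.ndarray, prs: np.ndarray,
                      start_cov: np.ndarray | None = None):
    """Wald z and p of a standardized PRS added to the covariate model.

    Uses the warm-started Newton solver (identical MLE to statsmodels;
    asserted by the test suite) so permutation loops stay cheap.
    """
    sd = prs.std()
    if sd == 0:
        return 0.0, 1.0, False
    prs_std = (prs - prs.mean()) / sd
    X = np.column_stack([X_cov, prs_std])
    start = None
    if start_cov is not None:
        start = np.append(start_cov, 0.0)
    beta, cov, _, converged = assoc.newton_logit(y, X, start=start)
    if not converged or cov is None:
        return np.nan, 1.0, False
    se = float(np.sqrt(cov[-1, -1]))
    z = float(beta[-1] / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p, True


def self_contained_test(prs, cohort: pd.DataFrame,
                        covariates: pd.DataFrame | None = None):
    """Covariate-adjusted association of one pathway PRS.

    Returns ``(z, p_self)`` with z = beta/SE from the logistic fit of
    status on the standardized PRS plus covariates.
    """
    y = cohort["STATUS"].to_numpy(dtype=float)
    X_cov = assoc.build_design(cohort, covariates)
    z, p, converged = _adjusted_prs_fit(y, X_cov, np.asarray(prs, dtype=float))
    if not converged:
        raise assoc.FitError("pathway association fit did not converge")
    return z, p


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PermutationBackground:
    """Pre-assembled genic background for size-matched permutation draws.

    ``dosages_eff`` are effect-allele dosages (flips applied) of the
    genic variants that survived genome-wide clumping, aligned with
    ``betas``; the covariate design, response and warm-start coefficients
    are fixed across draws.
    """

    snp_ids: np.ndarray
    dosages_eff: np.ndarray  # individuals x background variants
    betas: np.ndarray
    y: np.ndarray
    X_cov: np.ndarray
    start_cov: np.ndarray

    @property
    def size(self) -> int:
        return len(self.snp_ids)

    def score_subset(self, idx) -> np.ndarray:
        return self.dosages_eff[:, idx] @ self.betas[idx]

    def prs_p(self, prs: np.ndarray) -> float:
        """Self-contained p of an arbitrary score under this cohort/model."""
        _, p, _ = _adjusted_prs_fit(self.y, self.X_cov, prs, self.start_cov)
        return p


def make_background(genic_clump: ClumpResult, genotypes: GenotypeData,
                    cohort: pd.DataFrame,
                    covariates: pd.DataFrame | None = None) -> PermutationBackground:
    """Build the permutation background from post-clumping genic variants."""
    iv = genic_clump.index_variants
    idx = genotypes.variant_index(iv["SNP"])
    geno = genotypes.take_samples(cohort["IID"])
    D = np.asarray(geno.dosages[:, idx], dtype=np.float64)
    flip = iv["FLIP"].to_numpy(dtype=bool) if "FLIP" in iv else np.zeros(len(iv), bool)
    D_eff = np.where(flip[None, :], 2.0 - D, D)
    y = cohort["STATUS"].to_numpy(dtype=float)
    X_cov = assoc.build_design(cohort, covariates)
    beta_cov, _, _, converged = assoc.newton_logit(y, X_cov)
    if not converged:
        raise assoc.FitError("covariate-only fit did not converge")
    return PermutationBackground(
        snp_ids=iv["SNP"].to_numpy(),
        dosages_eff=D_eff,
        betas=iv["BETA"].to_numpy(dtype=float),
        y=y,
        X_cov=X_cov,
        start_cov=beta_cov,
    )


def competitive_p(observed_p_self: float, geneset_size_k: int,
                  background: PermutationBackground,
                  n_perm: int = 10_000, seed=0) -> float:
    """Competitive empirical p by size-matched background permutation.

    Each permutation draws k variants uniformly without replacement from
    the genic post-clumping background, scores them with their base-GWAS
    weights and records the covariate-adjusted association p; the
    competitive p is (#{p_perm ≤ observed} + 1)/(n_perm + 1).
    """
    k = int(geneset_size_k)
    if k <= 0:
        raise ValueError("gene-set size k must be positive")
    if k > background.size:
        raise ValueError(f"k={k} exceeds background size {background.size}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(background.size, size=k, replace=False)
        p_perm = background.prs_p(background.score_subset(idx))
        if p_perm <= observed_p_self:
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass
class ConcordanceResult:
    pearson_r: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pathways: int


def concordance(z_target, z_validation) -> ConcordanceResult:
    """Pearson correlation of paired pathway z-scores across cohorts,
    with Fisher-z 95% CI."""
    a = np.asarray(z_target, dtype=float)
    b = np.asarray(z_validation, dtype=float)
    if a.shape != b.shape:
        raise ValueError("z-score vectors must be paired")
    if len(a) < 3:
        raise ValueError("need at least 3 paired pathways")
    res = stats.pearsonr(a, b)
    ci = res.confidence_interval(0.95)
    return ConcordanceResult(pearson_r=float(res.statistic),
                             ci_low=float(ci.low), ci_high=float(ci.high),
                             p_value=float(res.pvalue), n_pathways=len(a))


def replication_filter(results_target: pd.DataFrame, results_validation: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Pathways FDR-significant in both cohorts with concordant direction."""
    merged = results_target.merge(results_validation, on="name",
                                  suffixes=("_target", "_validation"))
    keep = (
        (merged["q_fdr_target"] < alpha)
        & (merged["q_fdr_validation"] < alpha)
        & (np.sign(merged["z_target"]) == np.sign(merged["z_validation"]))
    )
    return merged[keep].reset_index(drop=True)


def run_pathway_analysis(gene_sets: dict[str, list[str]], gene_bed: pd.DataFrame,
                         panel: HarmonizedPanel, genotypes: GenotypeData,
                         cohort: pd.DataFrame,
                         covariates: pd.DataFrame | None = None,
                         clump_params: ClumpParams | None = None,
                         n_perm: int = 10_000, seed=0,
                         snp_lists: dict[str, list[str]] | None = None,
                         min_snps: int = 2) -> pd.DataFrame:
    """Score and test every pathway; returns one row per retained set.

    Columns: name, n_snp, z, p_self, q_fdr, p_comp, n_perm. When
    ``snp_lists`` is given (e.g. the clumped variant lists derived in the
    target cohort), those variants are scored directly instead of
    re-clumping — the cross-cohort transfer of a fitted model.
    """
    clump_params = clump_params or ClumpParams()
    snp_to_genes = map_snps_to_genes(panel.variants, gene_bed)

    # genic background after genome-wide clumping, for the competitive null
    genic_ids = set(snp_to_genes)
    genic_panel = HarmonizedPanel(
        variants=panel.variants[panel.variants["SNP"].isin(genic_ids)])
    if genic_panel.variants.empty:
        raise ValueError("no harmonized variant maps into a gene")
    genic_clump = clump(genic_panel, genotypes, clump_params)
    geno_cohort = genotypes.take_samples(cohort["IID"])
    background = make_background(genic_clump, genotypes, cohort, covariates)

    rows = []
    used_lists: dict[str, list[str]] = {}
    rng = np.random.default_rng(seed)
    for name, genes in gene_sets.items():
        if snp_lists is not None:
            kept = [s for s in snp_lists.get(name, [])
                    if s in set(panel.variants["SNP"])]
            if len(kept) < min_snps:
                logger.warning("pathway %s: <%d variants after transfer; skipped",
                               name, min_snps)
                continue
            sub = panel.variants[panel.variants["SNP"].isin(set(kept))]
            cres = ClumpResult(index_variants=sub.reset_index(drop=True))
            prs = score(geno_cohort, cres, thresholds=(1.0,)).scores[1.0]
            kept_ids = list(sub["SNP"])
        else:
            snps = geneset_snps(genes, snp_to_genes)
            if len(snps) < min_snps:
                logger.warning("pathway %s: %d mapped variants (<%d); skipped",
                               name, len(snps), min_snps)
                continue
            prs, cres = pathway_score(snps, panel, geno_cohort, clump_params)
            kept_ids = list(cres.index_variants["SNP"])
        used_lists[name] = kept_ids

        prs_vec = prs.to_numpy(dtype=float)
        z, p_self, converged = _adjusted_prs_fit(
            background.y, background.X_cov, prs_vec, background.start_cov)
        if not converged:
            logger.warning("pathway %s: association fit failed; skipped", name)
            continue
        p_comp = competitive_p(p_self, len(kept_ids), background,
                               n_perm=n_perm,
                               seed=rng.integers(0, 2**31 - 1))
        rows.append({"name": name, "n_snp": len(kept_ids), "z": z,
                     "p_self": p_self, "p_comp": p_comp, "n_perm": n_perm})

    if not rows:
        raise ValueError("no pathway retained enough variants to test")
    table = pd.DataFrame(rows)
    table["q_fdr"] = fdr_adjust(table["p_self"])
    table = table[["name", "n_snp", "z", "p_self", "q_fdr", "p_comp", "n_perm"]]
    table.attrs["snp_lists"] = used_lists
    table.attrs["background_size"] = background.size
    return table
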