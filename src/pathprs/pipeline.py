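"""End-to-end orchestration: simulate → harmonize → clump/score →
associate → pathway analysis, in memory or from files.

A single global seed is fanned out to per-stage child seeds through a
fixed SeedSequence rule, so stages are statistically independent but the
whole run is reproducible from one integer.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pathprs import assoc, io, pathway as pw, syndata
from pathprs.clumpscore import DEFAULT_THRESHOLDS, ClumpParams, clump, score, threshold_scan
from pathprs.containers import ClumpResult, GenotypeData, HarmonizedPanel, TrueModel
from pathprs.harmonize import compute_pcs, harmonize, qc_filter
from pathprs.syndata import SimulationConfig

logger = logging.getLogger(__name__)

__all__ = ["child_seed", "DemoData", "simulate_dataset", "genomewide_analysis",
           "run_study", "make_demo", "run_all"]


def child_seed(seed: int, stage: int) -> int:
    """Per-stage child of the global seed (fixed derivation rule)."""
    return int(np.random.SeedSequence([int(seed), int(stage)]).generate_state(1)[0]
               % (2**31 - 1))


@dataclass
class DemoData:
    """A fully synthetic two-cohort study with known ground truth."""

    sim_config: SimulationConfig
    genotypes_target: GenotypeData
    genotypes_validation: GenotypeData | None
    sumstats: pd.DataFrame
    cohort_target: pd.DataFrame
    cohort_validation: pd.DataFrame | None
    gene_bed: pd.DataFrame
    gene_sets: dict[str, list[str]]
    true_model: TrueModel
    true_model_validation: TrueModel | None
    enriched_pathway: str | None


def simulate_dataset(seed: int, *, n_individuals: int = 2000, n_variants: int = 5000,
                     n_blocks: int = 100, n_causal: int | None = None,
                     heritability: float = 0.3, n_genes: int = 200,
                     n_pathways: int = 40, pathway_size_range=(8, 25),
                     frac_intergenic: float = 0.3, enriched_frac: float = 0.75,
                     n_base: int = 458_554, two_cohorts: bool = True,
                     n_validation: int | None = None,
                     effect_sd: float = 0.05, **config_kwargs) -> DemoData:
    """Generate a complete synthetic study.

    One pathway (the first) is made causal-enriched by drawing
    ``enriched_frac`` of the causal variants from inside its genes; the
    remaining causal variants are scattered uniformly. The base GWAS
    sample size defaults to the scale of a biobank hypertension GWAS
    (144,793 cases + 313,761 controls).
    """
    if n_causal is None:
        n_causal = max(10, n_variants // 20)  # 5% of the panel is causal
    cfg = SimulationConfig(
        n_individuals=n_individuals, n_variants=n_variants, n_blocks=n_blocks,
        n_causal=n_causal, heritability_target=heritability,
        effect_sd=effect_sd, seed=child_seed(seed, 0), **config_kwargs,
    )
    genotypes = syndata.simulate_genotypes(cfg)
    gene_bed, gene_sets = syndata.simulate_annotation(
        genotypes.variants, n_genes=n_genes, n_pathways=n_pathways,
        pathway_size_range=pathway_size_range, frac_intergenic=frac_intergenic,
        seed=child_seed(seed, 1),
    )

    enriched = None
    candidate_ids = None
    if enriched_frac > 0 and gene_sets:
        enriched = next(iter(gene_sets))
        # the planted pathway's genes are made exclusive to it, so the
        # enrichment cannot leak into other sets through shared genes and
        # the scenario really contains one enriched pathway
        reserved = set(gene_sets[enriched])
        other_pool = np.array([g for g in gene_bed["GENE"] if g not in reserved])
        swap_rng = np.random.default_rng(child_seed(seed, 7))
        for name in list(gene_sets):
            if name == enriched:
                continue
            members = gene_sets[name]
            clean = [g for g in members if g not in reserved]
            n_replace = len(members) - len(clean)
            if n_replace:
                pool = np.setdiff1d(other_pool, clean)
                clean.extend(swap_rng.choice(pool, size=min(n_replace, len(pool)),
                                             replace=False))
            gene_sets[name] = sorted(clean)
        snp_to_genes = pw.map_snps_to_genes(genotypes.variants, gene_bed)
        candidate_ids = pw.geneset_snps(gene_sets[enriched], snp_to_genes)

    true_model = syndata.draw_true_model(
        genotypes.variants, n_causal=cfg.n_causal, effect_sd=cfg.effect_sd,
        seed=child_seed(seed, 2), candidate_ids=candidate_ids,
        candidate_frac=enriched_frac,
    )
    sumstats = syndata.simulate_base_gwas(genotypes, true_model, n_base=n_base,
                                          seed=child_seed(seed, 3))
    cohort_t = syndata.simulate_phenotype(genotypes, true_model, cfg,
                                          seed=child_seed(seed, 4))

    geno_v = cohort_v = tm_v = None
    if two_cohorts:
        geno_v = syndata.simulate_validation_genotypes(
            cfg, genotypes, n_validation or n_individuals, seed=child_seed(seed, 5))
        tm_v = copy.deepcopy(true_model)
        cohort_v = syndata.simulate_phenotype(geno_v, tm_v, cfg,
                                              seed=child_seed(seed, 6))

    return DemoData(sim_config=cfg, genotypes_target=genotypes,
                    genotypes_validation=geno_v, sumstats=sumstats,
                    cohort_target=cohort_t, cohort_validation=cohort_v,
                    gene_bed=gene_bed, gene_sets=gene_sets,
                    true_model=true_model, true_model_validation=tm_v,
                    enriched_pathway=enriched)


def genomewide_analysis(sumstats: pd.DataFrame, genotypes: GenotypeData,
                        cohort: pd.DataFrame, *,
                        thresholds=DEFAULT_THRESHOLDS,
                        clump_params: ClumpParams | None = None,
                        n_pcs: int = 4, maf_min: float = 0.01,
                        call_rate_min: float = 0.95,
                        clump_result: ClumpResult | None = None,
                        best_threshold: float | None = None) -> dict:
    """Genome-wide C+T PRS analysis of one cohort.

    When ``clump_result``/``best_threshold`` are supplied (a model fitted
    in another cohort), clumping and the threshold scan are skipped and
    the transferred variant list and weights are applied as-is.
    """
    clump_params = clump_params or ClumpParams()
    geno_qc = qc_filter(genotypes, maf_min=maf_min, call_rate_min=call_rate_min)
    panel = harmonize(sumstats, geno_qc.variants)
    geno_cohort = geno_qc.take_samples(cohort["IID"])
    pcs = compute_pcs(geno_cohort, n_pcs)

    if clump_result is None:
        cres = clump(panel, geno_cohort, clump_params)
    else:
        keep = clump_result.index_variants["SNP"].isin(set(panel.variants["SNP"]))
        cres = ClumpResult(
            index_variants=clump_result.index_variants[keep].reset_index(drop=True),
            clump_members=clump_result.clump_members)
    profile = score(geno_cohort, cres, thresholds)
    best, fit_table = threshold_scan(profile, cohort, pcs)
    if best_threshold is not None:
        best = float(best_threshold)

    prs_best = profile.scores[best].reindex(cohort["IID"]).to_numpy()
    result = assoc.prs_association(prs_best, cohort, pcs)
    deciles = assoc.decile_table(prs_best, cohort)

    y = cohort["STATUS"].to_numpy(dtype=float)
    X_cov = assoc.build_design(cohort, pcs)
    prs_std = (prs_best - prs_best.mean()) / prs_best.std()
    X_full = np.column_stack([X_cov, prs_std])
    fit_full = assoc.fit_logistic(y, X_full)
    fit_cov = assoc.fit_logistic(y, X_cov)
    pred_full = 1.0 / (1.0 + np.exp(-(X_full @ fit_full.params)))
    pred_cov = 1.0 / (1.0 + np.exp(-(X_cov @ fit_cov.params)))
    roc = assoc.delong_test(pred_full, pred_cov, y.astype(int))

    return {
        "panel": panel, "geno_qc": geno_qc, "geno_cohort": geno_cohort,
        "pcs": pcs, "clump": cres, "profile": profile,
        "best_threshold": best, "fit_table": fit_table,
        "association": result, "deciles": deciles, "roc": roc,
        "prs_best": prs_best,
    }


def run_study(data: DemoData, *, n_perm: int = 500, seed: int = 0,
              thresholds=DEFAULT_THRESHOLDS,
              clump_params: ClumpParams | None = None) -> dict:
    """Full study: genome-wide PRS in the target cohort, transfer to the
    validation cohort, pathway PRS with competitive permutation in both,
    FDR, replication and cross-cohort z-score concordance."""
    clump_params = clump_params or ClumpParams()
    out: dict = {}

    tgt = genomewide_analysis(data.sumstats, data.genotypes_target,
                              data.cohort_target, thresholds=thresholds,
                              clump_params=clump_params)
    out["target"] = tgt

    path_t = pw.run_pathway_analysis(
        data.gene_sets, data.gene_bed, tgt["panel"], tgt["geno_qc"],
        data.cohort_target, tgt["pcs"], clump_params=clump_params,
        n_perm=n_perm, seed=child_seed(seed, 10))
    out["pathways_target"] = path_t

    if data.cohort_validation is not None:
        val = genomewide_analysis(
            data.sumstats, data.genotypes_validation, data.cohort_validation,
            thresholds=thresholds, clump_params=clump_params,
            clump_result=tgt["clump"], best_threshold=tgt["best_threshold"])
        out["validation"] = val

        path_v = pw.run_pathway_analysis(
            data.gene_sets, data.gene_bed, val["panel"], val["geno_qc"],
            data.cohort_validation, val["pcs"], clump_params=clump_params,
            n_perm=n_perm, seed=child_seed(seed, 11),
            snp_lists=path_t.attrs["snp_lists"])
        out["pathways_validation"] = path_v

        merged = path_t.merge(path_v, on="name", suffixes=("_target", "_validation"))
        out["replicated"] = pw.replication_filter(path_t, path_v)
        out["concordance"] = pw.concordance(merged["z_target"],
                                            merged["z_validation"])
    return out


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------

def make_demo(outdir, seed: int = 1, **sim_kwargs) -> Path:
    """Write a ready-to-run synthetic study (data files + config.yaml)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(seed, **sim_kwargs)

    syndata.write_sumstats(data.sumstats, outdir / "base_sumstats.tsv")
    syndata.write_vcf(data.genotypes_target, outdir / "target.vcf")
    syndata.write_pheno(data.cohort_target, outdir / "target_pheno.tsv")
    syndata.write_bed(data.gene_bed, outdir / "genes.bed")
    syndata.write_gmt(data.gene_sets, outdir / "pathways.gmt")

    config = {
        "sumstats": str(outdir / "base_sumstats.tsv"),
        "vcf": str(outdir / "target.vcf"),
        "pheno": str(outdir / "target_pheno.tsv"),
        "bed": str(outdir / "genes.bed"),
        "gmt": str(outdir / "pathways.gmt"),
        "thresholds": list(DEFAULT_THRESHOLDS),
        "window_kb": 250.0,
        "r2_max": 0.1,
        "n_pcs": 4,
        "maf_min": 0.01,
        "call_rate_min": 0.95,
        "n_perm": 500,
        "seed": int(seed),
        "out": str(outdir / "report"),
    }
    if data.cohort_validation is not None:
        syndata.write_vcf(data.genotypes_validation, outdir / "validation.vcf")
        syndata.write_pheno(data.cohort_validation, outdir / "validation_pheno.tsv")
        config["validation_vcf"] = str(outdir / "validation.vcf")
        config["validation_pheno"] = str(outdir / "validation_pheno.tsv")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return outdir / "config.yaml"


def _load_cohort_inputs(vcf_path, pheno_path):
    genotypes = io.read_vcf(vcf_path)
    cohort = io.read_pheno(pheno_path)
    missing = set(cohort["IID"]) - set(genotypes.samples)
    if missing:
        raise ValueError(f"phenotype individuals absent from VCF: {sorted(missing)[:5]}")
    return genotypes, cohort


def run_all(config, outdir=None) -> Path:
    """Run the whole pipeline from a config mapping or YAML path.

    Writes the harmonized panel, per-threshold PRS, fit/decile/ROC
    tables, the pathway table (and replication + concordance when a
    validation cohort is configured) plus a manifest recording every
    parameter. Any stage failure propagates with its stage name.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(outdir or config.get("out", "report"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    clump_params = ClumpParams(window=float(config.get("window_kb", 250.0)),
                               r2_max=float(config.get("r2_max", 0.1)))
    thresholds = tuple(float(t) for t in config.get("thresholds", DEFAULT_THRESHOLDS))
    n_perm = int(config.get("n_perm", 10_000))

    stage = "read inputs"
    try:
        sumstats = io.read_sumstats(config["sumstats"])
        genotypes, cohort = _load_cohort_inputs(config["vcf"], config["pheno"])
        gene_bed = io.read_bed(config["bed"]) if "bed" in config else None
        gene_sets = io.read_gmt(config["gmt"]) if "gmt" in config else None

        stage = "genome-wide PRS (target)"
        tgt = genomewide_analysis(
            sumstats, genotypes, cohort, thresholds=thresholds,
            clump_params=clump_params, n_pcs=int(config.get("n_pcs", 4)),
            maf_min=float(config.get("maf_min", 0.01)),
            call_rate_min=float(config.get("call_rate_min", 0.95)))

        stage = "write genome-wide outputs"
        tgt["panel"].variants.to_csv(out / "panel.tsv", sep="\t", index=False)
        tgt["profile"].scores.to_csv(out / "prs_target.tsv", sep="\t")
        tgt["fit_table"].to_csv(out / "fit_table_target.tsv", sep="\t", index=False)
        tgt["deciles"].to_csv(out / "deciles_target.tsv", sep="\t", index=False)

        results_json = {
            "target": _summarize(tgt),
        }

        path_t = path_v = None
        if gene_bed is not None and gene_sets is not None:
            stage = "pathway PRS (target)"
            path_t = pw.run_pathway_analysis(
                gene_sets, gene_bed, tgt["panel"], tgt["geno_qc"], cohort,
                tgt["pcs"], clump_params=clump_params, n_perm=n_perm,
                seed=child_seed(seed, 10))
            path_t.to_csv(out / "pathways_target.tsv", sep="\t", index=False)

        if "validation_vcf" in config:
            stage = "genome-wide PRS (validation)"
            geno_v, cohort_v = _load_cohort_inputs(config["validation_vcf"],
                                                   config["validation_pheno"])
            val = genomewide_analysis(
                sumstats, geno_v, cohort_v, thresholds=thresholds,
                clump_params=clump_params, n_pcs=int(config.get("n_pcs", 4)),
                maf_min=float(config.get("maf_min", 0.01)),
                call_rate_min=float(config.get("call_rate_min", 0.95)),
                clump_result=tgt["clump"], best_threshold=tgt["best_threshold"])
            val["profile"].scores.to_csv(out / "prs_validation.tsv", sep="\t")
            val["deciles"].to_csv(out / "deciles_validation.tsv", sep="\t", index=False)
            results_json["validation"] = _summarize(val)

            if path_t is not None:
                stage = "pathway PRS (validation)"
                path_v = pw.run_pathway_analysis(
                    gene_sets, gene_bed, val["panel"], val["geno_qc"], cohort_v,
                    val["pcs"], clump_params=clump_params, n_perm=n_perm,
                    seed=child_seed(seed, 11), snp_lists=path_t.attrs["snp_lists"])
                path_v.to_csv(out / "pathways_validation.tsv", sep="\t", index=False)

                stage = "replication and concordance"
                repl = pw.replication_filter(path_t, path_v)
                repl.to_csv(out / "replicated_pathways.tsv", sep="\t", index=False)
                merged = path_t.merge(path_v, on="name",
                                      suffixes=("_target", "_validation"))
                conc = pw.concordance(merged["z_target"], merged["z_validation"])
                results_json["concordance"] = {
                    "pearson_r": conc.pearson_r, "ci_low": conc.ci_low,
                    "ci_high": conc.ci_high, "p_value": conc.p_value,
                    "n_pathways": conc.n_pathways,
                }
                results_json["n_replicated"] = int(len(repl))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(results_json, fh, indent=2)

    import pathprs
    manifest = {
        "package_version": pathprs.__version__,
        "seed": seed,
        "clump_window_kb": clump_params.window,
        "clump_r2_max": clump_params.r2_max,
        "thresholds": list(thresholds),
        "n_perm": n_perm,
        "config": {k: v for k, v in config.items()},
        "harmonization": tgt["panel"].summary(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("run_all: report written to %s", out)
    return out


def _summarize(res: dict) -> dict:
    a = res["association"]
    r = res["roc"]
    return {
        "best_threshold": res["best_threshold"],
        "n_index_variants": int(res["clump"].n_index),
        "n_variants_best": int(res["profile"].n_variants_used[res["best_threshold"]]),
        "beta_prs_per_sd": a.beta_prs,
        "p_value": a.p_value,
        "partial_nagelkerke_r2": a.partial_r2,
        "auc_full": r.auc_full,
        "auc_cov": r.auc_cov,
        "delong_p": r.delong_p,
        "n": a.n,
    }
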